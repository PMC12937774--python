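"""GVS stimulus library: waveform specs, synthesis, grouping, and JSON/CSV I/O.

The library holds 304 stimuli (one sham) organised into 37 waveform
categories, two of which (DC and sham) are singletons.  Waveform synthesis is
fully deterministic: the same spec and sampling rate always produce
bit-identical samples.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.signal import chirp as _chirp

FAMILIES = frozenset(
    {"DC", "sinusoid", "AM", "chirp", "chirpAM", "FM", "PAC", "multisine",
     "binary", "sham"}
)

N_STIMULI = 304
N_CATEGORIES = 37
SHAM_CATEGORY = 37
MAX_FREQ_HZ = 200.0


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulation waveform definition."""

    stim_id: int
    family: str
    params: dict = field(default_factory=dict)
    amplitude: float = 1.0
    category_id: int = 0
    category_label: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown waveform family: {self.family!r}")

    def to_dict(self) -> dict:
        return {
            "stim_id": self.stim_id,
            "family": self.family,
            "params": dict(self.params),
            "amplitude": self.amplitude,
            "category_id": self.category_id,
            "category_label": self.category_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(
            stim_id=int(d["stim_id"]),
            family=str(d["family"]),
            params=dict(d.get("params", {})),
            amplitude=float(d.get("amplitude", 1.0)),
            category_id=int(d["category_id"]),
            category_label=str(d.get("category_label", "")),
        )


def max_frequency(spec: StimulusSpec) -> float:
    """Highest frequency present in a spec (used for the Nyquist check)."""
    p = spec.params
    cands = [0.0]
    if "carrier_hz" in p:
        c = float(p["carrier_hz"])
        if spec.family == "FM":
            cands.append(c * (1.0 + float(p.get("depth", 0.0))))
        elif spec.family == "AM":
            cands.append(c + float(p.get("mod_hz", 0.0)))
        else:
            cands.append(c)
    for key in ("f0_hz", "f1_hz", "mod_hz", "pac_phase_hz", "pac_amp_hz"):
        if key in p:
            cands.append(float(p[key]))
    if spec.family == "PAC":
        cands.append(float(p.get("pac_amp_hz", 0.0)) + float(p.get("pac_phase_hz", 0.0)))
    if "freq_set" in p:
        cands.extend(float(f) for f in p["freq_set"])
    if "bit_rate_hz" in p:
        # square transitions; fundamental is bit_rate/2
        cands.append(float(p["bit_rate_hz"]))
    return max(cands)


def generate_waveform(spec: StimulusSpec, duration_s: float, fs: float) -> np.ndarray:
    """Synthesize the waveform for ``spec``; deterministic for a given fs."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    fmax = max_frequency(spec)
    if fs < 2.0 * fmax:
        raise ValueError(
            f"sampling rate {fs} Hz violates Nyquist for stimulus "
            f"{spec.stim_id} (max frequency {fmax} Hz)"
        )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    a = float(spec.amplitude)
    p = spec.params
    fam = spec.family

    if fam == "sham":
        return np.zeros(n)
    if fam == "DC":
        return np.full(n, a)
    if fam == "sinusoid":
        return a * np.sin(2 * np.pi * float(p["carrier_hz"]) * t)
    if fam == "AM":
        depth = float(p.get("depth", 1.0))
        env = (1.0 + depth * np.cos(2 * np.pi * float(p["mod_hz"]) * t)) / (1.0 + depth)
        return a * env * np.sin(2 * np.pi * float(p["carrier_hz"]) * t)
    if fam == "chirp":
        return a * _chirp(t, f0=float(p["f0_hz"]), t1=duration_s, f1=float(p["f1_hz"]))
    if fam == "chirpAM":
        depth = float(p.get("depth", 1.0))
        env = (1.0 + depth * np.cos(2 * np.pi * float(p["mod_hz"]) * t)) / (1.0 + depth)
        return a * env * _chirp(t, f0=float(p["f0_hz"]), t1=duration_s, f1=float(p["f1_hz"]))
    if fam == "FM":
        c = float(p["carrier_hz"])
        m = float(p["mod_hz"])
        depth = float(p.get("depth", 0.2))
        # instantaneous frequency c*(1 + depth*sin(2*pi*m*t)), integrated phase
        phase = 2 * np.pi * c * t + (c * depth / m) * (1.0 - np.cos(2 * np.pi * m * t))
        return a * np.sin(phase)
    if fam == "PAC":
        fp = float(p["pac_phase_hz"])
        fa = float(p["pac_amp_hz"])
        depth = float(p.get("depth", 0.9))
        env = (1.0 + depth * np.cos(2 * np.pi * fp * t)) / 2.0
        return a * env * np.sin(2 * np.pi * fa * t)
    if fam == "multisine":
        freqs = [float(f) for f in p["freq_set"]]
        k = np.arange(len(freqs))
        # Schroeder phases keep the crest factor low
        phases = -np.pi * k * (k + 1) / len(freqs)
        x = np.zeros(n)
        for f, ph in zip(freqs, phases):
            x += np.sin(2 * np.pi * f * t + ph)
        peak = np.max(np.abs(x))
        return a * x / peak if peak > 0 else x
    if fam == "binary":
        rate = float(p["bit_rate_hz"])
        seed = int(p.get("bit_seed", 0))
        n_bits = max(2, int(np.ceil(duration_s * rate)))
        n_bits += n_bits % 2  # even count so the sequence is balanced
        rng = np.random.default_rng(seed)
        bits = np.repeat([-1.0, 1.0], n_bits // 2)
        rng.shuffle(bits)
        spb = max(1, int(round(fs / rate)))
        x = np.repeat(bits, spb)[:n]
        if x.size < n:
            x = np.pad(x, (0, n - x.size), mode="edge")
        return a * x
    raise ValueError(f"unknown waveform family: {fam!r}")  # pragma: no cover


# --------------------------------------------------------------------------
# Default library construction
# --------------------------------------------------------------------------

_SINUSOID_BANDS = [
    (2, "Sinusoidal delta 1", 0.5, 1.0),
    (3, "Sinusoidal delta 2", 1.0, 2.0),
    (4, "Sinusoidal delta 3", 2.0, 4.0),
    (5, "Sinusoidal theta 1", 4.0, 6.0),
    (6, "Sinusoidal theta 2", 6.0, 8.0),
    (7, "Sinusoidal alpha 1", 8.0, 9.5),
    (8, "Sinusoidal alpha 2", 9.5, 11.0),
    (9, "Sinusoidal alpha 3", 11.0, 13.0),
    (10, "Sinusoidal beta 1", 13.0, 19.0),
    (11, "Sinusoidal beta 2", 19.0, 26.0),
    (12, "Sinusoidal beta 3", 26.0, 30.0),
    (13, "Sinusoidal gamma 1", 30.0, 60.0),
    (14, "Sinusoidal gamma 2", 60.0, 100.0),
    (15, "Sinusoidal high gamma", 100.0, 200.0),
]

_AM_CATS = [
    (16, "AM slow modulation", 40.0, [0.5, 1.0, 2.0, 4.0]),
    (17, "AM beta modulation", 80.0, [13.0, 16.0, 20.0, 26.0]),
    (18, "AM gamma modulation", 130.0, [30.0, 40.0, 50.0, 65.0]),
]

_CHIRP_PAIRS = [
    (0.5, 10.0), (0.5, 30.0), (1.0, 50.0), (5.0, 100.0),
    (10.0, 200.0), (13.0, 30.0), (30.0, 100.0), (50.0, 150.0),
]

_MULTISINE_CATS = [
    (20, "Multisine MVS",
     [[0.16, 0.33, 0.61, 1.03], [0.25, 0.55, 0.95, 1.45], [0.5, 1.1, 1.9, 2.9],
      [0.7, 1.3, 2.3, 3.7], [1.0, 2.2, 3.8, 5.4], [0.16, 0.33, 0.61, 1.03, 1.57],
      [0.25, 0.55, 0.95, 1.45, 2.05], [0.5, 1.1, 1.9, 2.9, 4.1]]),
    (21, "Multisine beta",
     [[13.0, 17.0, 21.0], [14.0, 19.0, 24.0], [15.0, 20.0, 25.0], [16.0, 22.0, 28.0],
      [13.0, 20.0, 27.0], [14.0, 21.0, 29.0], [13.0, 18.0, 23.0, 28.0],
      [15.0, 19.0, 23.0, 27.0]]),
    (22, "Multisine broadband",
     [[2.0, 10.0, 40.0], [4.0, 16.0, 64.0], [5.0, 25.0, 75.0], [8.0, 32.0, 96.0],
      [3.0, 12.0, 48.0], [6.0, 24.0, 72.0], [2.0, 8.0, 32.0, 96.0],
      [5.0, 20.0, 60.0, 100.0]]),
]

_FM_CARRIERS = [
    (28, 5.0), (29, 10.0), (30, 20.0), (31, 40.0),
    (32, 60.0), (33, 75.0), (34, 100.0), (35, 150.0),
]

_PAC_COMBOS = [
    (4.0, 65.0), (6.0, 65.0), (8.0, 65.0), (13.0, 65.0), (20.0, 65.0),
    (26.0, 65.0), (30.0, 65.0), (4.0, 100.0), (6.0, 100.0), (8.0, 100.0),
    (13.0, 100.0), (20.0, 100.0), (26.0, 100.0), (30.0, 100.0),
]


def build_default_library() -> list[StimulusSpec]:
    """Construct the packaged 304-stimulus / 37-category default library."""
    specs: list[StimulusSpec] = []
    sid = 1

    def add(family: str, params: dict, cat: int, label: str) -> None:
        nonlocal sid
        specs.append(StimulusSpec(stim_id=sid, family=family, params=params,
                                  amplitude=1.0, category_id=cat,
                                  category_label=label))
        sid += 1

    add("DC", {}, 1, "Direct current")

    for cat, label, lo, hi in _SINUSOID_BANDS:
        for f in np.round(np.linspace(lo, hi, 8), 3):
            add("sinusoid", {"carrier_hz": float(f)}, cat, label)

    for cat, label, carrier, mods in _AM_CATS:
        for mod in mods:
            for depth in (0.5, 1.0):
                add("AM", {"carrier_hz": carrier, "mod_hz": mod, "depth": depth},
                    cat, label)

    for f0, f1 in _CHIRP_PAIRS:
        add("chirp", {"f0_hz": f0, "f1_hz": f1}, 19, "Chirp up")

    for cat, label, sets in _MULTISINE_CATS:
        for fset in sets:
            add("multisine", {"freq_set": list(fset)}, cat, label)

    for f0, f1 in _CHIRP_PAIRS:
        add("chirp", {"f0_hz": f1, "f1_hz": f0}, 23, "Chirp down")

    for mod in (0.5, 1.0, 2.0, 4.0):
        for depth in (0.5, 1.0):
            add("chirpAM", {"f0_hz": 1.0, "f1_hz": 30.0, "mod_hz": mod,
                            "depth": depth}, 24, "Chirp-AM slow")
    for mod in (8.0, 13.0, 20.0, 30.0):
        for depth in (0.5, 1.0):
            add("chirpAM", {"f0_hz": 30.0, "f1_hz": 100.0, "mod_hz": mod,
                            "depth": depth}, 25, "Chirp-AM fast")

    for rate in (1.0, 2.0, 4.0, 8.0):
        for seed in (1, 2):
            add("binary", {"bit_rate_hz": rate, "bit_seed": seed}, 26,
                "Binary slow")
    for rate in (16.0, 32.0, 64.0, 128.0):
        for seed in (1, 2):
            add("binary", {"bit_rate_hz": rate, "bit_seed": seed}, 27,
                "Binary fast")

    for cat, carrier in _FM_CARRIERS:
        label = f"FM {carrier:g} Hz carrier"
        for mod in (0.5, 1.0, 2.0, 4.0, 8.0):
            for depth in (0.1, 0.3):
                add("FM", {"carrier_hz": carrier, "mod_hz": mod, "depth": depth},
                    cat, label)

    for fp, fa in _PAC_COMBOS:
        add("PAC", {"pac_phase_hz": fp, "pac_amp_hz": fa, "depth": 0.9}, 36,
            "Phase–Amplitude Coupling")

    add("sham", {}, SHAM_CATEGORY, "Sham")

    assert len(specs) == N_STIMULI
    return specs


def category_sizes(library: Iterable[StimulusSpec]) -> dict[int, int]:
    sizes: dict[int, int] = {}
    for s in library:
        sizes[s.category_id] = sizes.get(s.category_id, 0) + 1
    return sizes


def nonsingleton_categories(library: Iterable[StimulusSpec]) -> list[int]:
    """Category ids with more than one member, ascending."""
    return sorted(c for c, n in category_sizes(library).items() if n > 1)


def sham_spec(library: Iterable[StimulusSpec]) -> StimulusSpec:
    shams = [s for s in library if s.family == "sham"]
    if len(shams) != 1:
        raise ValueError(f"library must contain exactly one sham, found {len(shams)}")
    return shams[0]


def save_library(library: list[StimulusSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in library], fh, indent=1)


def load_library(path) -> list[StimulusSpec]:
    with open(path) as fh:
        return [StimulusSpec.from_dict(d) for d in json.load(fh)]


def save_grouping_csv(library: list[StimulusSpec], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["stim_id", "category_id", "category_label"])
        for s in library:
            w.writerow([s.stim_id, s.category_id, s.category_label])
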
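"""DNA structural-property profiles and promoter peak/cleft detection.

A property scale maps every di- or trinucleotide to a physico-chemical
value (bendability, base stacking energy, ...).  Converting a sequence
word-by-word gives the raw profile; a centered moving average of window
3 nt and step 1 gives the smoothed profile.  Human core promoters show a
wide peak (bendability, nucleosome positioning, propeller twist, DNA
denaturation) or cleft (A-philicity, base stacking, Z-DNA, B-DNA twist)
near the TSS, which the detector scores as a robust z-magnitude against
the flank baseline.

The packaged scale tables are editable TSV defaults approximating
published experimental scales; code and tests never depend on the
specific numbers, only on the file contract (complete over 4^k words,
fixed direction per property).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .seqio import SequenceRecord

#: peak-or-cleft orientation per shipped property
DIRECTIONS = {
    "bendability": "peak",
    "nucleosome_positioning": "peak",
    "propeller_twist": "peak",
    "dna_denaturation": "peak",
    "a_philicity": "cleft",
    "base_stacking": "cleft",
    "z_dna": "cleft",
    "b_dna_twist": "cleft",
}

SMOOTH_WINDOW = 3  # nt, fixed smoothing of the raw profile
_BASE_INDEX = {"a": 0, "c": 1, "g": 2, "t": 3}


@dataclass(frozen=True)
class PropertyScale:
    """A complete word -> value table with a fixed extremum direction."""

    name: str
    k: int
    values: Dict[str, float]
    direction: str

    def __post_init__(self) -> None:
        if self.k not in (2, 3):
            raise ValueError("word size k must be 2 or 3")
        if self.direction not in ("peak", "cleft"):
            raise ValueError("direction must be 'peak' or 'cleft'")
        if len(self.values) != 4 ** self.k:
            raise ValueError(
                f"scale {self.name}: expected {4 ** self.k} words, "
                f"got {len(self.values)}"
            )

    def lookup_array(self) -> np.ndarray:
        """Values indexed by base-4 word code (a=0, c=1, g=2, t=3)."""
        arr = np.empty(4 ** self.k)
        for word, val in self.values.items():
            code = 0
            for b in word:
                code = code * 4 + _BASE_INDEX[b]
            arr[code] = val
        return arr


def load_scale(path: str | Path) -> PropertyScale:
    """Load a scale TSV: '# property:', '# k:', '# direction:' headers
    then word<TAB>value rows."""
    meta: Dict[str, str] = {}
    values: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            word, val = line.split("\t")
            values[word.lower()] = float(val)
    return PropertyScale(
        meta.get("property", Path(path).stem),
        int(meta["k"]),
        values,
        meta["direction"],
    )


def builtin_scale_names() -> List[str]:
    return sorted(DIRECTIONS)


def builtin_scale(name: str) -> PropertyScale:
    """Load one of the packaged property scales by name."""
    if name not in DIRECTIONS:
        raise KeyError(f"unknown property {name!r}; see builtin_scale_names()")
    ref = resources.files("gramprom").joinpath(f"data/scales/{name}.tsv")
    with resources.as_file(ref) as path:
        return load_scale(path)


@dataclass
class StructuralProfile:
    """Raw and window-3 smoothed per-position property values."""

    property_name: str
    k: int
    direction: str
    values: np.ndarray    # length len(seq) - k + 1
    smoothed: np.ndarray  # length len(values) - SMOOTH_WINDOW + 1

    def __len__(self) -> int:
        return len(self.values)


def structural_profile(record: SequenceRecord, scale: PropertyScale) -> StructuralProfile:
    """Word-by-word conversion of *record* followed by window-3 smoothing.

    Words containing 'n' are undefined on the scale; the caller must mask
    or split around assembly gaps first.
    """
    seq = record.seq
    k = scale.k
    if len(seq) < k + SMOOTH_WINDOW - 1:
        raise ValueError(f"sequence shorter than k + {SMOOTH_WINDOW - 1}")
    if "n" in seq:
        raise ValueError("sequence contains 'n'; mask before profiling")
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    base = np.empty(codes.shape, dtype=np.int64)
    for ch, idx in _BASE_INDEX.items():
        base[codes == ord(ch)] = idx
    word_codes = base[: len(seq) - k + 1].copy()
    for offset in range(1, k):
        word_codes = word_codes * 4 + base[offset : len(seq) - k + 1 + offset]
    raw = scale.lookup_array()[word_codes]
    kernel = np.ones(SMOOTH_WINDOW) / SMOOTH_WINDOW
    smoothed = np.convolve(raw, kernel, mode="valid")
    return StructuralProfile(scale.name, k, scale.direction, raw, smoothed)


@dataclass(frozen=True)
class ExtremumCall:
    """A detected peak/cleft candidate with its robust z-magnitude.

    ``position`` indexes into the window sequence (0-based).  ``passes``
    is True iff |magnitude| >= threshold with the sign matching the
    property's direction.
    """

    position: int
    magnitude: float
    kind: str
    passes: bool


def detect_extremum(
    profile: StructuralProfile,
    center_lo: int,
    center_hi: int,
    threshold: float,
    feature_width: int = 50,
) -> ExtremumCall:
    """Score the strongest peak/cleft inside ``[center_lo, center_hi)``.

    Baseline and spread are the median and scaled MAD (x1.4826, floored
    at 1e-9) of the smoothed profile *outside* the center region.  The
    candidate value is the extreme of a ``feature_width`` moving average
    of the smoothed profile within the center: the promoter signature is
    a wide extremum, and averaging at feature scale separates it from
    single-position noise (``feature_width=1`` recovers a pointwise
    detector).  Magnitude is (value - baseline)/spread, signed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sm = profile.smoothed
    center_lo = max(0, center_lo)
    center_hi = min(len(sm), center_hi)
    if center_hi <= center_lo:
        raise ValueError("center region is empty")
    outside = np.concatenate([sm[:center_lo], sm[center_hi:]])
    if outside.size == 0:
        outside = sm  # degenerate: whole profile is center
    baseline = float(np.median(outside))
    spread = max(float(np.median(np.abs(outside - baseline))) * 1.4826, 1e-9)

    w = max(1, min(feature_width, len(sm)))
    avg = np.convolve(sm, np.ones(w) / w, mode="valid")
    # averaged index m covers smoothed [m, m+w); restrict to windows
    # centered inside the center region
    lo = int(np.clip(center_lo - w // 2, 0, len(avg) - 1))
    hi = int(np.clip(center_hi - w // 2, lo + 1, len(avg)))
    segment = avg[lo:hi]
    if profile.direction == "peak":
        arg = int(np.argmax(segment))
    else:
        arg = int(np.argmin(segment))
    value = float(segment[arg])
    magnitude = (value - baseline) / spread
    # position in window-sequence coordinates: center of the averaged span
    position = lo + arg + w // 2 + SMOOTH_WINDOW // 2 + profile.k // 2
    sign_ok = magnitude > 0 if profile.direction == "peak" else magnitude < 0
    passes = sign_ok and abs(magnitude) >= threshold
    return ExtremumCall(position, magnitude, profile.direction, passes)


def aggregate_profiles(profiles: Sequence[StructuralProfile]) -> np.ndarray:
    """Mean smoothed profile across records (reporting-only plumbing)."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    n = min(len(p.smoothed) for p in profiles)
    return np.mean([p.smoothed[:n] for p in profiles], axis=0)


def profile_to_tsv(profile: StructuralProfile, path: str | Path) -> None:
    """Wiggle-like TSV: position, raw value, smoothed value (where defined)."""
    with open(path, "w") as fh:
        fh.write(f"# property: {profile.property_name}\n")
        for i, v in enumerate(profile.values):
            # smoothed[j] is centered on raw position j+1
            j = i - SMOOTH_WINDOW // 2
            sm = (
                f"{profile.smoothed[j]:.4f}"
                if 0 <= j < len(profile.smoothed)
                else "."
            )
            fh.write(f"{i}\t{v:.4f}\t{sm}\n")


def plot_mean_profiles(
    aggregates: Dict[str, np.ndarray],
    out_path: str | Path,
    tss_offset: Optional[int] = None,
) -> None:
    """Plot population-average profiles per property (one panel each)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(aggregates)
    fig, axes = plt.subplots(n, 1, figsize=(8, 2.2 * n), sharex=True)
    if n == 1:
        axes = [axes]
    for ax, (name, series) in zip(axes, sorted(aggregates.items())):
        ax.plot(series, lw=0.8)
        ax.set_ylabel(name, fontsize=7)
        if tss_offset is not None:
            ax.axvline(tss_offset, color="red", lw=0.6, ls="--")
    axes[-1].set_xlabel("window position (nt)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
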
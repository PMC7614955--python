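"""Transmembrane-helix prediction by sliding-window hydropathy scanning.

Integral-membrane NAD(P) transhydrogenase carries its proton-translocating
domain II as a bundle of TM helices.  This module finds candidate helices
as maximal runs of residues whose windowed mean Kyte-Doolittle hydropathy
clears a threshold, and groups consecutive helices into *stretches* —
helix runs uninterrupted by a large soluble region.  The αβ isoform shows
a single stretch of 14 helices; the βα isoform two stretches of typically
9 and 4.

This is a deliberately simple, deterministic scanner intended for
synthetic/desk-scale sequences; output from a dedicated topology predictor
can be substituted through :func:`nthiso.domain_scan.parse_external_annotations`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .config import DEFAULT_CONFIG

__all__ = [
    "KYTE_DOOLITTLE",
    "TMHelix",
    "TMStretch",
    "hydropathy_profile",
    "predict_tm_helices",
    "group_stretches",
]


def _load_scale() -> dict[str, float]:
    text = resources.files("nthiso.fixtures").joinpath("kyte_doolittle.tsv").read_text()
    scale: dict[str, float] = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            res, value = line.split("\t")
            scale[res] = float(value)
    return scale


#: Kyte-Doolittle hydropathy indices for the 20 canonical amino acids.
KYTE_DOOLITTLE: dict[str, float] = _load_scale()

_CANONICAL = set(KYTE_DOOLITTLE)


@dataclass(frozen=True)
class TMHelix:
    """One predicted transmembrane helix, 0-based half-open coordinates."""

    start: int
    end: int
    mean_hydropathy: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid helix interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TMStretch:
    """A run of consecutive TM helices uninterrupted by a large soluble region."""

    helices: tuple[TMHelix, ...]

    def __post_init__(self) -> None:
        if not self.helices:
            raise ValueError("a stretch needs at least one helix")

    @property
    def start(self) -> int:
        return self.helices[0].start

    @property
    def end(self) -> int:
        return self.helices[-1].end

    @property
    def n_helices(self) -> int:
        return len(self.helices)


# ----------------------------------------------------------------------
def hydropathy_profile(sequence: str, window: int = DEFAULT_CONFIG.window) -> np.ndarray:
    """Per-residue mean Kyte-Doolittle hydropathy over a centered window.

    Windows are truncated at the termini, so position ``i`` averages over
    ``sequence[max(0, i-w//2) : i+w//2+1]``.  ``X`` scores 0.0; any other
    non-canonical character is an error.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if window < 5 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 5, got {window}")
    if window > len(sequence):
        raise ValueError(
            f"window ({window}) exceeds sequence length ({len(sequence)})"
        )
    values = np.empty(len(sequence))
    for i, aa in enumerate(sequence):
        if aa == "X":
            values[i] = 0.0
        elif aa in _CANONICAL:
            values[i] = KYTE_DOOLITTLE[aa]
        else:
            raise ValueError(f"non-canonical residue {aa!r} at position {i}")
    half = window // 2
    # cumulative-sum trick handles the truncated terminal windows exactly
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(len(sequence))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, len(sequence))
    return (csum[hi] - csum[lo]) / (hi - lo)


def _runs_above(profile: np.ndarray, threshold: float) -> list[list[int]]:
    """Maximal [start, end) runs with profile >= threshold."""
    above = profile >= threshold
    runs: list[list[int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    return runs


def _split_long_run(start: int, end: int, profile: np.ndarray,
                    min_len: int, max_len: int) -> list[tuple[int, int]]:
    """Recursively split a run longer than ``max_len``.

    The cut goes at the lowest-profile position among interior positions
    that leave both pieces at least ``min_len`` long (leftmost minimum on
    ties); if no such position exists the run is trimmed to ``max_len``.
    """
    if end - start <= max_len:
        return [(start, end)]
    lo, hi = start + min_len, end - min_len
    if lo >= hi:
        return [(start, start + max_len)]
    cut = lo + int(np.argmin(profile[lo:hi]))
    return (_split_long_run(start, cut, profile, min_len, max_len)
            + _split_long_run(cut, end, profile, min_len, max_len))


def predict_tm_helices(
    sequence: str,
    *,
    window: int = DEFAULT_CONFIG.window,
    threshold: float = DEFAULT_CONFIG.threshold,
    min_helix_len: int = DEFAULT_CONFIG.min_helix_len,
    max_helix_len: int = DEFAULT_CONFIG.max_helix_len,
    min_loop_len: int = DEFAULT_CONFIG.min_loop_len,
) -> list[TMHelix]:
    """Predict TM helices from hydropathy runs.

    Maximal above-threshold runs are found on the windowed profile; runs
    separated by fewer than ``min_loop_len`` residues are merged; runs
    longer than ``max_helix_len`` are split recursively at interior
    hydropathy minima; runs shorter than ``min_helix_len`` are extended
    symmetrically into free flanking sequence.  The result is sorted and
    non-overlapping, and deterministic for fixed inputs.
    """
    if min(window, min_helix_len, max_helix_len, min_loop_len) <= 0:
        raise ValueError("all parameters must be positive")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    profile = hydropathy_profile(sequence, window)
    runs = _runs_above(profile, threshold)
    if not runs:
        return []
    # merge runs separated by less than min_loop_len
    merged: list[list[int]] = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < min_loop_len:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # split over-long runs
    pieces: list[tuple[int, int]] = []
    for s, e in merged:
        pieces.extend(_split_long_run(s, e, profile, min_helix_len, max_helix_len))
    # extend under-short pieces into free space (left first on odd deficits)
    n = len(sequence)
    bounded: list[list[int]] = [list(p) for p in pieces]
    for k, piece in enumerate(bounded):
        deficit = min_helix_len - (piece[1] - piece[0])
        if deficit <= 0:
            continue
        left_free = piece[0] - (bounded[k - 1][1] if k > 0 else 0)
        right_free = (bounded[k + 1][0] if k + 1 < len(bounded) else n) - piece[1]
        take_left = min(left_free, (deficit + 1) // 2)
        take_right = min(right_free, deficit - take_left)
        if take_left + take_right < deficit:  # rebalance onto the freer side
            take_left = min(left_free, deficit - take_right)
        piece[0] -= take_left
        piece[1] += min(take_right, deficit - take_left)
    raw = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in sequence])
    return [
        TMHelix(s, e, float(raw[s:e].mean())) for s, e in bounded
    ]


def group_stretches(
    helices: Sequence[TMHelix],
    split_points: Iterable[tuple[int, int]] = (),
    max_gap: int = DEFAULT_CONFIG.max_gap,
) -> list[TMStretch]:
    """Group sorted helices into stretches.

    Consecutive helices share a stretch iff the gap between them is at most
    ``max_gap`` residues *and* no ``split_points`` interval (e.g. a soluble
    domain hit) lies wholly inside the gap.
    """
    hs = list(helices)
    for a, b in zip(hs, hs[1:]):
        if b.start < a.end:
            raise ValueError(f"helices unsorted or overlapping at [{b.start}, {b.end})")
    splits = sorted(tuple(p) for p in split_points)
    for (a0, a1), (b0, b1) in zip(splits, splits[1:]):
        if b0 < a1:
            raise ValueError("split_points intervals overlap")
    if not hs:
        return []
    groups: list[list[TMHelix]] = [[hs[0]]]
    for prev, cur in zip(hs, hs[1:]):
        gap = (prev.end, cur.start)
        split_here = cur.start - prev.end > max_gap or any(
            gap[0] <= s0 and s1 <= gap[1] for s0, s1 in splits
        )
        if split_here:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    return [TMStretch(tuple(g)) for g in groups]
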
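"""Locating the NAD(H)- and NADP(H)-binding domains by motif scanning.

Functional transhydrogenase carries a nucleotide-binding domain I
(NAD(H)) and domain III (NADP(H)); their N→C order is what defines the
αβ versus βα isoform.  Domains are located here with small position score
matrices built from Rossmann-fold-style consensus strings (including the
classical GXGXXG dinucleotide-binding fingerprint).  The matrices are a
functional, download-free stand-in for profile-HMM domain annotation;
tables from real annotation tools can be supplied instead via
:func:`parse_external_annotations`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tm_scan import TMHelix

__all__ = [
    "DOMAIN_I",
    "DOMAIN_III",
    "AMINO_ACIDS",
    "DomainHit",
    "MotifLibrary",
    "build_default_library",
    "score_motif",
    "find_domains",
    "parse_external_annotations",
]

DOMAIN_I = "DOMAIN_I"
DOMAIN_III = "DOMAIN_III"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Consensus strings authored in-repo.  Domain I carries the classical
# GXGXXG dinucleotide-binding fingerprint (GGGVAG); domain III is kept
# deliberately dissimilar so the two kinds cannot cross-match.
_CONSENSUS = {
    DOMAIN_I: "VAVVGGGVAGLSAAYELAKQGYEV",
    DOMAIN_III: "RIAIPRESAFPMERRVAITPEMVK",
}


@dataclass(frozen=True)
class DomainHit:
    """An accepted motif hit, 0-based half-open coordinates."""

    kind: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.kind not in (DOMAIN_I, DOMAIN_III):
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid hit interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class MotifLibrary:
    """Per-kind position score matrix plus acceptance threshold.

    ``matrices[kind]`` has one row per motif position and 21 columns: the
    20 canonical residues in :data:`AMINO_ACIDS` order plus a trailing
    all-zero column used to score ``X``.
    """

    matrices: Mapping[str, np.ndarray]
    thresholds: Mapping[str, float]
    consensus: Mapping[str, str]

    def __post_init__(self) -> None:
        for kind, m in self.matrices.items():
            if not np.isfinite(m).all():
                raise ValueError(f"non-finite scores in {kind} matrix")
            if m.shape[0] < 6:
                raise ValueError(f"{kind} motif shorter than 6 positions")

    def max_score(self, kind: str) -> float:
        return float(self.matrices[kind].max(axis=1).sum())


def build_default_library(
    match_score: float = 4.0, threshold_frac: float = 0.6
) -> MotifLibrary:
    """Build the packaged consensus-string motif library.

    Each matrix scores ``match_score`` for the consensus residue and 0
    otherwise; the acceptance threshold is ``threshold_frac`` of the
    maximum achievable score, far above what unplanted background
    sequence can reach.
    """
    matrices: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    for kind, cons in _CONSENSUS.items():
        m = np.zeros((len(cons), 21))
        for p, aa in enumerate(cons):
            m[p, _AA_INDEX[aa]] = match_score
        matrices[kind] = m
        thresholds[kind] = threshold_frac * match_score * len(cons)
    return MotifLibrary(matrices, thresholds, dict(_CONSENSUS))


DEFAULT_LIBRARY = build_default_library()


def _encode(sequence: str) -> np.ndarray:
    idx = np.empty(len(sequence), dtype=int)
    for i, aa in enumerate(sequence):
        if aa == "X":
            idx[i] = 20
        elif aa in _AA_INDEX:
            idx[i] = _AA_INDEX[aa]
        else:
            raise ValueError(f"non-canonical residue {aa!r} at position {i}")
    return idx


def score_motif(sequence: str, matrix: np.ndarray) -> np.ndarray:
    """Score every alignment offset of ``matrix`` against ``sequence``.

    Returns one summed score per offset (length ``len(sequence) -
    motif_len + 1``); a motif longer than the sequence yields an empty
    array with a warning.
    """
    motif_len = matrix.shape[0]
    if motif_len > len(sequence):
        warnings.warn(
            f"motif length {motif_len} exceeds sequence length {len(sequence)}",
            stacklevel=2,
        )
        return np.empty(0)
    idx = _encode(sequence)
    n_offsets = len(sequence) - motif_len + 1
    scores = np.zeros(n_offsets)
    for p in range(motif_len):
        scores += matrix[p, idx[p : p + n_offsets]]
    return scores


def find_domains(
    sequence: str,
    library: MotifLibrary = DEFAULT_LIBRARY,
    max_hits_per_kind: int = 2,
) -> list[DomainHit]:
    """Greedy best-score-first selection of non-overlapping motif hits.

    Per kind, offsets scoring at or above the library threshold are
    accepted best-first (ties broken by smaller start) while they do not
    overlap an already accepted hit of the same kind, up to
    ``max_hits_per_kind``.  Hits are returned sorted by start.
    """
    hits: list[DomainHit] = []
    for kind, matrix in library.matrices.items():
        scores = score_motif(sequence, matrix)
        if scores.size == 0:
            continue
        thr = library.thresholds[kind]
        candidates = sorted(
            ((float(scores[o]), o) for o in np.flatnonzero(scores >= thr)),
            key=lambda t: (-t[0], t[1]),
        )
        taken: list[tuple[int, int]] = []
        motif_len = matrix.shape[0]
        for score, offset in candidates:
            if len(taken) >= max_hits_per_kind:
                break
            iv = (int(offset), int(offset) + motif_len)
            if all(iv[1] <= s or iv[0] >= e for s, e in taken):
                taken.append(iv)
                hits.append(DomainHit(kind, iv[0], iv[1], score))
    return sorted(hits, key=lambda h: h.start)


# ----------------------------------------------------------------------
_FEATURE_MAP = {
    "NAD_binding": DOMAIN_I,
    "NADP_binding": DOMAIN_III,
    "TMhelix": "TMhelix",
}


def parse_external_annotations(
    table: str | Path | pd.DataFrame | Iterable[tuple],
) -> dict[str, tuple[list[DomainHit], list[TMHelix]]]:
    """Parse an external domain/TM annotation table.

    The canonical dialect is a TSV with columns ``protein_id``,
    ``feature_type`` (``NAD_binding`` | ``NADP_binding`` | ``TMhelix``),
    ``start``, ``end`` in **1-based inclusive** coordinates (the
    convention of common annotation servers); they are converted to the
    package's 0-based half-open convention.  Returns, per protein, the
    domain hits (score ``nan``: externally validated) and TM helices.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep="\t")
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame(
            list(table), columns=["protein_id", "feature_type", "start", "end"]
        )
    required = {"protein_id", "feature_type", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")

    out: dict[str, tuple[list[DomainHit], list[TMHelix]]] = {}
    for row in df.itertuples(index=False):
        ftype = str(row.feature_type)
        if ftype not in _FEATURE_MAP:
            raise ValueError(f"unknown feature_type in row {tuple(row)!r}")
        start1, end1 = int(row.start), int(row.end)
        if end1 < start1:
            raise ValueError(f"end < start in row {tuple(row)!r}")
        start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        doms, helices = out.setdefault(str(row.protein_id), ([], []))
        if ftype == "TMhelix":
            helices.append(TMHelix(start, end, math.nan))
        else:
            doms.append(DomainHit(_FEATURE_MAP[ftype], start, end, math.nan))
    for doms, helices in out.values():
        doms.sort(key=lambda h: h.start)
        helices.sort(key=lambda h: h.start)
        for a, b in zip(helices, helices[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping TM helices [{a.start},{a.end}) / [{b.start},{b.end})"
                )
    return out
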
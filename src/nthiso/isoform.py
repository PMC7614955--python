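"""Isoform classification from per-protein domain architecture.

Eukaryotic NAD(P) transhydrogenase is a single chain in one of two
configurations: αβ, with the NAD(H)-binding domain I amino-terminal to
the NADP(H)-binding domain III and a single stretch of 14 TM helices
between them, or the inverted βα configuration with the β-subunit
portion first (TM stretch of ~9 helices, domain III, domain I, TM
stretch of ~4).  The configuration call is decided by domain order
alone; TM stretch structure is characteristic and only sets quality
flags.  Because domains I and III must sit on the same side of the
membrane for hydride transfer, the number of TM helices strictly
between them must be even — an odd count marks a physically impossible
(INVALID) architecture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from . import domain_scan, tm_scan
from .config import DEFAULT_CONFIG, RunConfig
from .domain_scan import DOMAIN_I, DOMAIN_III, DomainHit, MotifLibrary
from .tm_scan import TMHelix, TMStretch

__all__ = [
    "ALPHA_BETA",
    "BETA_ALPHA",
    "AMBIGUOUS",
    "INVALID",
    "ArchElement",
    "Architecture",
    "IsoformTemplate",
    "DEFAULT_TEMPLATES",
    "IsoformCall",
    "assemble_architecture",
    "parity_check",
    "classify_isoform",
    "classify_sequence",
    "classify_batch",
]

ALPHA_BETA = "ALPHA_BETA"
BETA_ALPHA = "BETA_ALPHA"
AMBIGUOUS = "AMBIGUOUS"
INVALID = "INVALID"

TM_STRETCH = "TM_STRETCH"

# QC flags
MISSING_DOMAIN_I = "MISSING_DOMAIN_I"
MISSING_DOMAIN_III = "MISSING_DOMAIN_III"
PARITY_VIOLATION = "PARITY_VIOLATION"
TM_COUNT_DEVIATION = "TM_COUNT_DEVIATION"
STRETCH_COUNT_DEVIATION = "STRETCH_COUNT_DEVIATION"


@dataclass(frozen=True)
class ArchElement:
    kind: str                      # DOMAIN_I | DOMAIN_III | TM_STRETCH
    start: int
    end: int
    stretch: TMStretch | None = None

    @property
    def n_helices(self) -> int:
        return self.stretch.n_helices if self.stretch is not None else 0


@dataclass(frozen=True)
class Architecture:
    """Ordered, non-overlapping elements of one protein chain."""

    elements: tuple[ArchElement, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.elements, self.elements[1:]):
            if b.start < a.end:
                raise ValueError("architecture elements overlap or are unsorted")
        for kind in (DOMAIN_I, DOMAIN_III):
            if sum(e.kind == kind for e in self.elements) > 1:
                raise ValueError(f"more than one {kind} element")

    def domain(self, kind: str) -> ArchElement | None:
        for e in self.elements:
            if e.kind == kind:
                return e
        return None

    @property
    def stretches(self) -> tuple[ArchElement, ...]:
        return tuple(e for e in self.elements if e.kind == TM_STRETCH)

    @property
    def helices(self) -> tuple[TMHelix, ...]:
        out: list[TMHelix] = []
        for e in self.stretches:
            out.extend(e.stretch.helices)
        return tuple(out)


@dataclass(frozen=True)
class IsoformTemplate:
    label: str
    element_order: tuple[str, ...]
    helix_counts: tuple[int, ...]   # per TM_STRETCH element, in order

    def __post_init__(self) -> None:
        if self.element_order.count(TM_STRETCH) != len(self.helix_counts):
            raise ValueError("helix_counts do not match TM_STRETCH elements")


#: αβ: domain I — 14-helix stretch — domain III.
#: βα: 9-helix stretch — domain III — domain I — 4-helix stretch.
DEFAULT_TEMPLATES: dict[str, IsoformTemplate] = {
    ALPHA_BETA: IsoformTemplate(
        ALPHA_BETA, (DOMAIN_I, TM_STRETCH, DOMAIN_III), (14,)
    ),
    BETA_ALPHA: IsoformTemplate(
        BETA_ALPHA, (TM_STRETCH, DOMAIN_III, DOMAIN_I, TM_STRETCH), (9, 4)
    ),
}


@dataclass(frozen=True)
class IsoformCall:
    label: str
    flags: frozenset[str]
    template_deviation: tuple[int, ...]   # signed per-stretch helix-count differences
    between_helices: int | None = None    # helices strictly between domains I and III

    def __post_init__(self) -> None:
        if self.label in (ALPHA_BETA, BETA_ALPHA):
            bad = {MISSING_DOMAIN_I, MISSING_DOMAIN_III, PARITY_VIOLATION}
            if self.flags & bad:
                raise ValueError(f"{self.label} call carries blocking flags {self.flags}")
        if self.label == INVALID and PARITY_VIOLATION not in self.flags:
            raise ValueError("INVALID requires PARITY_VIOLATION")


# ----------------------------------------------------------------------
def assemble_architecture(
    domain_hits: Sequence[DomainHit], stretches: Sequence[TMStretch]
) -> Architecture:
    """Merge domain hits and TM stretches into one sorted element list.

    A stretch overlapping a domain hit is truncated at the domain
    boundary: helices falling inside the hit are trimmed to the outside
    part (dropped when nothing remains) and the surviving helices are
    re-grouped on either side of the domain.
    """
    for kind in (DOMAIN_I, DOMAIN_III):
        if sum(h.kind == kind for h in domain_hits) > 1:
            raise ValueError(
                f"multiple {kind} hits passed to assembly; select upstream"
            )
    intervals = sorted((h.start, h.end) for h in domain_hits)
    parts: list[TMStretch] = []
    for stretch in stretches:
        groups: list[list[TMHelix]] = [[]]
        for helix in stretch.helices:
            s, e = helix.start, helix.end
            for d0, d1 in intervals:
                if s < d1 and d0 < e:  # overlap: keep the larger outside part
                    if s < d0 and (d0 - s) >= (e - d1):
                        e = d0
                    elif e > d1:
                        s = d1
                    else:
                        s = e = d0  # fully swallowed
            if e - s <= 0:
                groups.append([])  # swallowed helix splits the stretch
                continue
            trimmed = TMHelix(s, e, helix.mean_hydropathy)
            # a domain strictly between the previous kept helix and this one splits
            if groups[-1] and any(
                groups[-1][-1].end <= d0 and d1 <= trimmed.start
                for d0, d1 in intervals
            ):
                groups.append([trimmed])
            else:
                groups[-1].append(trimmed)
        parts.extend(TMStretch(tuple(g)) for g in groups if g)
    elements = [
        ArchElement(h.kind, h.start, h.end) for h in domain_hits
    ] + [ArchElement(TM_STRETCH, s.start, s.end, s) for s in parts]
    elements.sort(key=lambda e: (e.start, e.end))
    return Architecture(tuple(elements))


def parity_check(architecture: Architecture) -> tuple[str, int]:
    """Count TM helices strictly between domains I and III.

    Returns ``("VALID", n)`` when the count is even — domains I and III
    end up on the same membrane side — else ``("PARITY_VIOLATION", n)``.
    Order-agnostic; both domains must be present.
    """
    d1 = architecture.domain(DOMAIN_I)
    d3 = architecture.domain(DOMAIN_III)
    if d1 is None or d3 is None:
        raise ValueError("parity_check requires both domains present")
    lo, hi = sorted([d1, d3], key=lambda e: e.start)
    count = sum(
        1 for h in architecture.helices if h.start >= lo.end and h.end <= hi.start
    )
    return ("VALID" if count % 2 == 0 else PARITY_VIOLATION), count


def classify_isoform(
    architecture: Architecture,
    templates: dict[str, IsoformTemplate] = DEFAULT_TEMPLATES,
    tolerance: int = DEFAULT_CONFIG.helix_tolerance,
) -> IsoformCall:
    """Call the isoform of one architecture.

    The label is decided by domain order alone: ALPHA_BETA iff domain I
    starts before domain III, BETA_ALPHA iff after.  A missing domain
    gives AMBIGUOUS; an odd between-domain helix count gives INVALID.
    Stretch structure departing from the matching template by more than
    ``tolerance`` helices only sets deviation flags.
    """
    if not {ALPHA_BETA, BETA_ALPHA} <= set(templates):
        raise ValueError("templates must cover both isoform labels")
    d1 = architecture.domain(DOMAIN_I)
    d3 = architecture.domain(DOMAIN_III)
    flags: set[str] = set()
    if d1 is None:
        flags.add(MISSING_DOMAIN_I)
    if d3 is None:
        flags.add(MISSING_DOMAIN_III)
    if flags:
        return IsoformCall(AMBIGUOUS, frozenset(flags), ())
    status, between = parity_check(architecture)
    if status == PARITY_VIOLATION:
        return IsoformCall(INVALID, frozenset({PARITY_VIOLATION}), (), between)
    label = ALPHA_BETA if d1.start < d3.start else BETA_ALPHA
    expected = templates[label].helix_counts
    observed = tuple(e.n_helices for e in architecture.stretches)
    deviation: tuple[int, ...] = ()
    if len(observed) != len(expected):
        flags.add(STRETCH_COUNT_DEVIATION)
    else:
        deviation = tuple(o - e for o, e in zip(observed, expected))
        if any(abs(d) > tolerance for d in deviation):
            flags.add(TM_COUNT_DEVIATION)
    return IsoformCall(label, frozenset(flags), deviation, between)


# ----------------------------------------------------------------------
def classify_sequence(
    sequence: str,
    config: RunConfig = DEFAULT_CONFIG,
    library: MotifLibrary = domain_scan.DEFAULT_LIBRARY,
) -> tuple[Architecture, IsoformCall]:
    """Full single-sequence pipeline: scan, assemble, classify."""
    helices = tm_scan.predict_tm_helices(
        sequence,
        window=config.window,
        threshold=config.threshold,
        min_helix_len=config.min_helix_len,
        max_helix_len=config.max_helix_len,
        min_loop_len=config.min_loop_len,
    )
    hits = domain_scan.find_domains(sequence, library, config.max_hits_per_kind)
    stretches = tm_scan.group_stretches(
        helices, [(h.start, h.end) for h in hits], config.max_gap
    )
    arch = assemble_architecture(hits, stretches)
    return arch, classify_isoform(arch, tolerance=config.helix_tolerance)


def classify_batch(
    records: Iterable, config: RunConfig = DEFAULT_CONFIG
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify many protein records; never abort on one bad record.

    Returns ``(table, summary)``: one row per input protein (order
    preserved; failures become label ERROR rows) plus per-lineage label
    counts — the survey-table analogue.
    """
    rows = []
    for rec in records:
        try:
            arch, call = classify_sequence(rec.sequence, config)
            rows.append(
                {
                    "protein_id": rec.id,
                    "genus": rec.genus,
                    "lineage": rec.lineage,
                    "label": call.label,
                    "flags": ";".join(sorted(call.flags)),
                    "stretch_sizes": ",".join(
                        str(e.n_helices) for e in arch.stretches
                    ),
                }
            )
        except Exception as exc:  # record-level failure, pipeline continues
            rows.append(
                {
                    "protein_id": rec.id,
                    "genus": rec.genus,
                    "lineage": rec.lineage,
                    "label": "ERROR",
                    "flags": str(exc),
                    "stretch_sizes": "",
                }
            )
    columns = ["protein_id", "genus", "lineage", "label", "flags", "stretch_sizes"]
    table = pd.DataFrame(rows, columns=columns)
    summary = (
        table.groupby(["lineage", "label"]).size().rename("count").reset_index()
        if len(table)
        else pd.DataFrame(columns=["lineage", "label", "count"])
    )
    return table, summary
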
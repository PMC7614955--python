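"""File formats and packaged fixtures.

FASTA for protein records (with an optional TSV metadata join), newick
for trees, TSV for every table.  Coordinates are 0-based half-open in
all machine outputs; the only 1-based boundary is the external
annotation table handled in :mod:`nthiso.domain_scan`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .domain_scan import AMINO_ACIDS, DomainHit
from .gene_content import GeneRecord, PresenceAbsenceMatrix
from .tm_scan import TMStretch

__all__ = [
    "ProteinRecord",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "write_elements_tsv",
    "read_gene_records",
    "write_gene_records",
    "fixture_path",
    "load_fixture_matrix",
    "load_topologies",
    "load_complements",
    "load_group_references",
]

_VALID_ALPHABET = set(AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein chain with its survey metadata."""

    id: str
    genus: str
    lineage: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} has non-canonical residues {sorted(bad)}"
            )


# ----------------------------------------------------------------------
def read_fasta(
    path: str | Path, metadata: str | Path | pd.DataFrame | None = None
) -> list[ProteinRecord]:
    """Read protein FASTA; headers are ``id [genus] [lineage]``.

    Sequences are upper-cased; wrapped lines are concatenated.  An
    optional TSV with columns ``id``, ``genus``, ``lineage`` overrides
    header metadata.  Duplicate ids are an error; an empty file yields
    an empty list with a warning.
    """
    meta: dict[str, tuple[str, str]] = {}
    if metadata is not None:
        df = (
            metadata
            if isinstance(metadata, pd.DataFrame)
            else pd.read_csv(metadata, sep="\t")
        )
        for row in df.itertuples(index=False):
            meta[str(row.id)] = (str(row.genus), str(row.lineage))
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        rid = tokens[0]
        if rid in seen:
            raise ValueError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        genus = tokens[1] if len(tokens) > 1 else ""
        lineage = tokens[2] if len(tokens) > 2 else ""
        if rid in meta:
            genus, lineage = meta[rid]
        records.append(ProteinRecord(rid, genus, lineage, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description=" ".join(t for t in (r.genus, r.lineage) if t),
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ----------------------------------------------------------------------
def read_newick(path: str | Path) -> TreeNode:
    """Read one newick tree; quoted labels and missing branch lengths OK."""
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValueError(f"could not parse newick file {path}: {exc}") from exc


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ----------------------------------------------------------------------
def write_elements_tsv(
    elements: dict[str, tuple[Sequence[DomainHit], Sequence[TMStretch]]],
    path: str | Path,
) -> None:
    """Write per-protein architecture elements (0-based half-open)."""
    rows = []
    for protein_id, (hits, stretches) in elements.items():
        for h in hits:
            rows.append((protein_id, h.kind, h.start, h.end))
        for s in stretches:
            rows.append((protein_id, f"TM_STRETCH({s.n_helices})", s.start, s.end))
            for helix in s.helices:
                rows.append((protein_id, "TM_HELIX", helix.start, helix.end))
    pd.DataFrame(
        rows, columns=["protein_id", "element_type", "start", "end"]
    ).to_csv(path, sep="\t", index=False)


def read_gene_records(path: str | Path) -> list[GeneRecord]:
    # keep_default_na: "NA" is the no-paralogue-group sentinel, not a missing value
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        GeneRecord(
            str(r.lineage), str(r.gene_id), str(r.isoform), str(r.paralog_group)
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_records(records: Iterable[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.lineage, r.gene_id, r.isoform, r.paralog_group) for r in records],
        columns=["lineage", "gene_id", "isoform", "paralog_group"],
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture."""
    path = Path(str(resources.files("nthiso.fixtures").joinpath(name)))
    if not path.exists():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return path


def load_fixture_matrix() -> PresenceAbsenceMatrix:
    """The packaged lineage × character loss/retention matrix."""
    return PresenceAbsenceMatrix.from_tsv(fixture_path("table2.tsv"))


def load_topologies(names: Sequence[str] = ("janouskovec", "mathur", "salomaki")) -> dict[str, TreeNode]:
    """The packaged candidate apicomplexan topologies, rooted, by name."""
    return {name: read_newick(fixture_path(f"{name}.nwk")) for name in names}


def load_complements() -> list[GeneRecord]:
    """The packaged per-lineage gene-complement table."""
    return read_gene_records(fixture_path("complements.tsv"))


def load_group_references() -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Packaged synthetic reference sequences for paralogue groups I/II."""
    records = read_fasta(fixture_path("synthetic_group_refs.fasta"))
    refs_i = [(r.id, r.sequence) for r in records if r.lineage == "GROUP_I"]
    refs_ii = [(r.id, r.sequence) for r in records if r.lineage == "GROUP_II"]
    return refs_i, refs_ii
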
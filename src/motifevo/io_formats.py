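"""Readers and writers for FASTA, aligned FASTA, Newick and taxonomy TSV.

No science lives here: these functions validate and normalize external
files into the in-memory types the rest of the package operates on.
FASTA parsing is delegated to Biopython, Newick parsing to dendropy.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import dendropy
from Bio import SeqIO

PathLike = Union[str, Path]

#: The 20 canonical amino acids.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Residue alphabet accepted in sequence files: canonical residues plus the
#: unknown-residue placeholder 'X'.
SEQ_ALPHABET = AMINO_ACIDS | {"X"}
#: Canonical gap character.  '.' is tolerated on input and normalized.
GAP = "-"


class FormatError(ValueError):
    """Raised for malformed or contract-violating input files."""


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped protein sequence with a unique identifier."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id {self.id!r} is empty or contains whitespace")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-amino-acid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TaxonRecord:
    """A taxon with its ordered lineage, coarsest rank first."""

    taxon_id: str
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.lineage:
            raise FormatError(f"taxon {self.taxon_id!r} has an empty lineage")

    def rank(self, depth: int) -> str:
        """Lineage label at 1-based ``depth``; the finest label if shallower."""
        return self.lineage[min(depth, len(self.lineage)) - 1]


def _check_unique_ids(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id {i!r}")
        seen.add(i)


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read an ungapped protein FASTA file.

    Gap characters are rejected; use :func:`read_alignment` for gapped
    input.  Lowercase residues are uppercased.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if GAP in seq or "." in seq:
            raise FormatError(
                f"sequence {rec.id!r} in {path} contains gap characters; "
                "use read_alignment for aligned input"
            )
        bad = set(seq) - SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {rec.id!r} in {path} contains non-amino-acid "
                f"characters: {sorted(bad)}"
            )
        desc = "" if rec.description == rec.id else rec.description
        records.append(SequenceRecord(id=rec.id, residues=seq, description=desc))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    _check_unique_ids((r.id for r in records), "sequence")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: PathLike, width: int = 60) -> None:
    _check_unique_ids((r.id for r in records), "sequence")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            desc = rec.description
            if desc and desc != rec.id and not desc.startswith(rec.id + " "):
                header = f"{rec.id} {desc}"
            elif desc and desc.startswith(rec.id + " "):
                header = desc
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: PathLike):
    """Read an aligned FASTA file into an :class:`AlignmentMatrix`.

    All rows must have equal length.  '.' gaps are normalized to '-'.
    """
    from motifevo.alignment_stats import AlignmentMatrix

    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        row = str(rec.seq).upper().replace(".", GAP)
        bad = set(row) - SEQ_ALPHABET - {GAP}
        if bad:
            raise FormatError(
                f"row {rec.id!r} in {path} contains invalid characters: {sorted(bad)}"
            )
        ids.append(rec.id)
        rows.append(row)
    if not rows:
        raise FormatError(f"no FASTA records found in {path}")
    _check_unique_ids(ids, "sequence")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        expected = len(rows[0])
        ragged = [i for i, r in zip(ids, rows) if len(r) != expected]
        raise FormatError(f"ragged alignment rows in {path}: {ragged}")
    return AlignmentMatrix(ids=tuple(ids), rows=tuple(rows))


def write_alignment(aln, path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, row in zip(aln.ids, aln.rows):
            fh.write(f">{seq_id}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def read_newick(source: PathLike) -> dendropy.Tree:
    """Read a single rooted Newick tree with unique leaf labels.

    Multifurcations are allowed; branch lengths and internal-node labels
    (e.g. posterior supports) are preserved but unused downstream.
    """
    text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise FormatError(f"could not parse Newick in {source}: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels in {source}: {dupes}")
    return tree


def parse_newick_string(text: str) -> dendropy.Tree:
    """Parse a Newick string (same contract as :func:`read_newick`)."""
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".nwk", delete=False) as fh:
        fh.write(text)
        name = fh.name
    try:
        return read_newick(name)
    finally:
        Path(name).unlink(missing_ok=True)


def write_newick(tree: dendropy.Tree, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                unquoted_underscores=True,
                suppress_rooting=True,
            )
        )


def read_taxonomy(path: PathLike) -> list[TaxonRecord]:
    """Read a taxonomy TSV with columns ``taxon_id`` and ``lineage``.

    The lineage cell holds semicolon-separated rank labels ordered from
    domain to species.  Comment lines starting with '#' are skipped.
    """
    records: list[TaxonRecord] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if "taxon_id" not in header or "lineage" not in header:
                    raise FormatError(
                        f"taxonomy file {path} must have columns 'taxon_id' and "
                        f"'lineage'; found header {header}"
                    )
                continue
            row = dict(zip(header, fields))
            taxon_id = row.get("taxon_id", "").strip()
            lineage_cell = row.get("lineage", "").strip()
            if not taxon_id:
                raise FormatError(f"{path}:{lineno}: empty taxon_id")
            if not lineage_cell:
                raise FormatError(f"{path}:{lineno}: empty lineage for taxon {taxon_id!r}")
            lineage = tuple(r.strip() for r in lineage_cell.split(";") if r.strip())
            if not lineage:
                raise FormatError(f"{path}:{lineno}: empty lineage for taxon {taxon_id!r}")
            records.append(TaxonRecord(taxon_id=taxon_id, lineage=lineage))
    if header is None:
        raise FormatError(f"taxonomy file {path} is empty")
    _check_unique_ids((r.taxon_id for r in records), "taxon")
    return records


def write_taxonomy(records: Sequence[TaxonRecord], path: PathLike) -> None:
    _check_unique_ids((r.taxon_id for r in records), "taxon")
    with open(path, "w") as fh:
        fh.write("taxon_id\tlineage\n")
        for rec in records:
            fh.write(f"{rec.taxon_id}\t{';'.join(rec.lineage)}\n")


def tsv_header_comment(tool: str, **params) -> str:
    """Standard commented header naming the tool version and parameters."""
    from motifevo import __version__

    parts = [f"motifevo={__version__}", f"tool={tool}"]
    parts += [f"{k}={v}" for k, v in params.items()]
    return "# " + " ".join(parts) + "\n"
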
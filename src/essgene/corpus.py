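"""Reading DEG-style corpora: paired DNA/protein FASTA plus cluster tables.

Curated essential-gene collections distribute, per species and per class
(essential / non-essential), one nucleotide FASTA and one protein FASTA
whose records correspond one-to-one.  Headers vary between dialects, so
records are matched on the first whitespace-delimited token of the header
by default (a custom regular expression can be supplied).

Orthology cluster membership — as emitted by an external clustering tool —
is consumed as a two-column delimited file mapping gene id to cluster id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidInputError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """One labeled gene: paired DNA/protein sequence with metadata."""

    gene_id: str
    species: str
    dna: str
    protein: str
    essential: bool
    cluster_id: str | None = None

    def __post_init__(self):
        if not self.dna or not self.protein:
            raise InvalidInputError(
                f"{self.gene_id}: DNA and protein sequences must be non-empty"
            )


@dataclass(frozen=True)
class ClusterMap:
    """Gene-id to orthology-cluster-id assignments."""

    assignments: dict[str, str]

    def __len__(self) -> int:
        return len(self.assignments)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))


def _index_fasta(path: str | Path, id_pattern: str | None) -> dict[str, str]:
    """FASTA -> {identifier: sequence}; duplicate identifiers are an error."""
    regex = re.compile(id_pattern) if id_pattern else None
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if regex is not None:
            m = regex.search(rec.description)
            if not m:
                raise InvalidInputError(
                    f"{path}: header {rec.description!r} does not match "
                    f"id pattern {id_pattern!r}"
                )
            ident = m.group(1) if m.groups() else m.group(0)
        else:
            ident = rec.id  # first whitespace-delimited token
        if ident in out:
            raise InvalidInputError(f"{path}: duplicated identifier {ident!r}")
        out[ident] = str(rec.seq)
    return out


def read_labeled_fasta_pair(
    dna_path: str | Path,
    protein_path: str | Path,
    species: str,
    essential: bool,
    id_pattern: str | None = None,
) -> list[GeneRecord]:
    """Pair a DNA FASTA with its protein FASTA into labeled GeneRecords.

    Records present in only one of the two files are logged as warnings
    and skipped; record order follows the DNA file.  Zero matched pairs is
    an error.
    """
    dna_seqs = _index_fasta(dna_path, id_pattern)
    prot_seqs = _index_fasta(protein_path, id_pattern)
    only_dna = set(dna_seqs) - set(prot_seqs)
    only_prot = set(prot_seqs) - set(dna_seqs)
    for ident in sorted(only_dna):
        log.warning("%s: %s has no protein record, skipped", dna_path, ident)
    for ident in sorted(only_prot):
        log.warning("%s: %s has no DNA record, skipped", protein_path, ident)
    records = [
        GeneRecord(ident, species, dna_seqs[ident], prot_seqs[ident], essential)
        for ident in dna_seqs
        if ident in prot_seqs
    ]
    if not records:
        raise InvalidInputError(
            f"no identifier shared between {dna_path} and {protein_path}"
        )
    log.info(
        "%s: %d gene records (%d unmatched skipped)",
        species,
        len(records),
        len(only_dna) + len(only_prot),
    )
    return records


def write_fasta_pair(
    records: list[GeneRecord], dna_path: str | Path, protein_path: str | Path
) -> None:
    """Write records back out as a matched DNA/protein FASTA pair."""
    SeqIO.write(
        (SeqRecord(Seq(r.dna), id=r.gene_id, description="") for r in records),
        str(dna_path),
        "fasta",
    )
    SeqIO.write(
        (SeqRecord(Seq(r.protein), id=r.gene_id, description="") for r in records),
        str(protein_path),
        "fasta",
    )


def read_cluster_map(path: str | Path, delimiter: str | None = None) -> ClusterMap:
    """Read a two-column (gene_id, cluster_id) table.

    Blank lines and ``#`` comments are ignored.  A gene mapped to two
    different clusters is a contradiction and raises.
    """
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected two columns, got {line!r}"
                )
            gene_id, cluster_id = parts[0], parts[1]
            if gene_id in assignments and assignments[gene_id] != cluster_id:
                raise InvalidInputError(
                    f"{path}: gene {gene_id!r} assigned to both "
                    f"{assignments[gene_id]!r} and {cluster_id!r}"
                )
            assignments[gene_id] = cluster_id
    return ClusterMap(assignments)


def write_cluster_map(cmap: ClusterMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tcluster_id\n")
        for gene_id, cluster_id in cmap.assignments.items():
            fh.write(f"{gene_id}\t{cluster_id}\n")


def attach_clusters(
    records: list[GeneRecord], cmap: ClusterMap
) -> list[GeneRecord]:
    """Set each record's cluster id; unmapped genes become singletons.

    A singleton cluster id is derived from the gene id so that genes absent
    from the clustering output never share a cluster.
    """
    return [
        replace(
            rec,
            cluster_id=cmap.assignments.get(rec.gene_id, f"singleton:{rec.gene_id}"),
        )
        for rec in records
    ]
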
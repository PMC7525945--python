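"""Sequence-derived features for gene essentiality prediction.

Every gene/protein pair is represented by 89 numbers with a fixed layout:

==========================  =====  ========================================
block                       width  contents
==========================  =====  ========================================
codon frequencies              64  in-frame codon counts / total complete
                                   codons, codons in lexicographic order
                                   AAA..TTT
GC content                      1  (G+C) / (A+C+G+T), ambiguity codes
                                   excluded
gene length                     1  nucleotides of the CDS (incl. stop)
CAI                             1  codon adaptation index, range (0, 1]
RSCU_max                        1  maximum relative synonymous codon usage
                                   over degenerate non-stop families
amino-acid frequencies         20  one-letter codes in alphabetical order
protein length                  1  counted standard residues (no trailing *)
==========================  =====  ========================================

Codon-level statistics use a configurable NCBI genetic-code table
(bacterial table 11 by default).  Stop codons form their own synonymous
family; methionine, tryptophan and stop codons never contribute to CAI or
to RSCU_max.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .errors import ConfigurationError, InvalidInputError

#: the 64 codons in lexicographic order, the canonical layout everywhere
CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=3)
)
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

#: the 20 standard amino acids in alphabetical one-letter order
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

DEFAULT_GENETIC_CODE = 11

#: fixed 89-name layout of the feature vector
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"codon_{c}" for c in CODONS)
    + ("gc_content", "gene_length", "cai", "rscu_max")
    + tuple(f"aa_{a}" for a in AMINO_ACIDS)
    + ("protein_length",)
)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 89


@functools.lru_cache(maxsize=None)
def _synonymous_families(code: int) -> dict[str, tuple[str, ...]]:
    """Map amino acid (or '*') to its tuple of synonymous codons."""
    try:
        table = CodonTable.unambiguous_dna_by_id[code]
    except KeyError as exc:
        raise ConfigurationError(f"unknown genetic-code table id: {code}") from exc
    families: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        families.setdefault(aa, []).append(codon)
    families["*"] = list(table.stop_codons)
    return {aa: tuple(sorted(cods)) for aa, cods in families.items()}


def codon_to_aa(code: int = DEFAULT_GENETIC_CODE) -> dict[str, str]:
    """Codon -> amino acid (stops mapped to ``'*'``) under table ``code``."""
    return {
        codon: aa
        for aa, codons in _synonymous_families(code).items()
        for codon in codons
    }


@dataclass(frozen=True)
class CodonCounts:
    """In-frame codon counts of a single DNA sequence.

    ``total`` is the number of complete, unambiguous codons counted.
    """

    counts: dict[str, int]
    total: int

    def __post_init__(self):
        bad = set(self.counts) - set(CODONS)
        if bad:
            raise InvalidInputError(f"non-canonical codon keys: {sorted(bad)}")
        if sum(self.counts.values()) != self.total:
            raise InvalidInputError("codon counts do not sum to total")

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = dict(self.counts)
        for codon, n in other.counts.items():
            merged[codon] = merged.get(codon, 0) + n
        return CodonCounts(merged, self.total + other.total)


@dataclass(frozen=True)
class RscuTable:
    """Relative synonymous codon usage values under a genetic code."""

    rscu: dict[str, float]
    code: int


@dataclass(frozen=True)
class AdaptednessTable:
    """Per-codon relative adaptedness r_i in (0, 1] used by CAI.

    ``excluded`` lists codons that are never scored (Met, Trp, stops, and
    members of families entirely unobserved in the reference).
    """

    r: dict[str, float]
    excluded: frozenset[str]
    source: str = "unspecified reference"


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 89-value numeric representation of one gene/protein pair."""

    values: np.ndarray
    layout: tuple[str, ...] = field(default=FEATURE_NAMES, repr=False)

    def __post_init__(self):
        if self.values.shape != (N_FEATURES,):
            raise InvalidInputError(
                f"feature vector must have exactly {N_FEATURES} values, "
                f"got shape {self.values.shape}"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.layout, self.values.tolist()))


def count_codons(dna: str, record_id: str = "<sequence>") -> CodonCounts:
    """Count non-overlapping in-frame codons from position 0.

    A trailing incomplete triplet is discarded; triplets containing any
    non-ACGT character (IUPAC ambiguity codes) are skipped and do not
    contribute to the total.
    """
    if not dna:
        raise InvalidInputError(f"{record_id}: empty DNA sequence")
    seq = dna.upper()
    counts: dict[str, int] = {}
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in _CODON_INDEX:
            counts[codon] = counts.get(codon, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise InvalidInputError(
            f"{record_id}: no complete unambiguous codon in sequence"
        )
    return CodonCounts(counts, total)


def codon_frequencies(counts: CodonCounts) -> np.ndarray:
    """Normalize codon counts to a 64-vector summing to 1 (AAA..TTT order)."""
    if counts.total < 1:
        raise InvalidInputError("cannot normalize zero codon counts")
    freq = np.zeros(64)
    for codon, n in counts.counts.items():
        freq[_CODON_INDEX[codon]] = n
    return freq / counts.total


def gc_content(dna: str, record_id: str = "<sequence>") -> float:
    """Fraction of G/C among unambiguous bases."""
    seq = dna.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        raise InvalidInputError(f"{record_id}: no unambiguous A/C/G/T base")
    return gc / (gc + at)


def rscu(counts: CodonCounts, code: int = DEFAULT_GENETIC_CODE) -> RscuTable:
    """Relative synonymous codon usage: RSCU_i = X_i / (S/n).

    ``S`` is the total count of codon ``i``'s synonymous family and ``n``
    the family's degeneracy.  A family with S = 0 gets RSCU 0 for all of
    its codons.  Stop codons form their own family.
    """
    table: dict[str, float] = {}
    for _aa, family in _synonymous_families(code).items():
        n = len(family)
        s = sum(counts[c] for c in family)
        for c in family:
            table[c] = counts[c] / (s / n) if s > 0 else 0.0
    return RscuTable(table, code)


def rscu_max(table: RscuTable) -> float:
    """Maximum RSCU over degenerate (n >= 2) non-stop families.

    Met and Trp sit in singleton families under the bacterial code and are
    excluded along with stops; an all-zero table yields 0.
    """
    best = 0.0
    for aa, family in _synonymous_families(table.code).items():
        if aa == "*" or len(family) < 2:
            continue
        for c in family:
            best = max(best, table.rscu[c])
    return best


def relative_adaptedness(
    reference: CodonCounts, code: int = DEFAULT_GENETIC_CODE
) -> AdaptednessTable:
    """Relative adaptedness r_i = X_i / X_max within each synonymous family.

    ``X_max`` is the count of the family's most frequent codon in the
    reference set, so each observed family's top codon has r = 1.  An
    unobserved codon in an observed family gets the pseudo-value
    ``0.5 / X_max`` so that CAI never reaches exactly 0.  Met, Trp, stop
    codons and entirely unobserved families are excluded from scoring.
    """
    if reference.total == 0:
        raise InvalidInputError("adaptedness reference has zero codon counts")
    r: dict[str, float] = {}
    excluded: set[str] = set()
    for aa, family in _synonymous_families(code).items():
        if aa == "*" or len(family) < 2:
            excluded.update(family)
            continue
        x_max = max(reference[c] for c in family)
        if x_max == 0:
            excluded.update(family)
            continue
        for c in family:
            x = reference[c]
            r[c] = x / x_max if x > 0 else 0.5 / x_max
    return AdaptednessTable(r, frozenset(excluded))


def cai(gene: CodonCounts, table: AdaptednessTable) -> float:
    """Codon adaptation index: geometric mean of r over scored codon uses.

    Each codon occurrence contributes one term; Met, Trp, stops and
    unscored codons are skipped.  Computed in log space for stability.
    """
    log_sum = 0.0
    n_scored = 0
    for codon, count in gene.counts.items():
        r = table.r.get(codon)
        if r is None:
            continue
        log_sum += count * math.log(r)
        n_scored += count
    if n_scored == 0:
        raise InvalidInputError(
            "gene has no codon scored by the adaptedness table "
            "(only Met/Trp/stop or unobserved families)"
        )
    return math.exp(log_sum / n_scored)


def aa_frequencies(protein: str, record_id: str = "<protein>") -> np.ndarray:
    """Frequencies of the 20 standard amino acids (A..Y order).

    Non-standard letters (B, J, O, U, X, Z) are skipped and excluded from
    the denominator; a single trailing ``*`` is permitted and ignored.
    """
    seq = protein.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    freq = np.zeros(20)
    n = 0
    for ch in seq:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            freq[idx] += 1
            n += 1
    if n == 0:
        raise InvalidInputError(f"{record_id}: no standard amino-acid residue")
    return freq / n


def counted_protein_length(protein: str) -> int:
    """Number of standard residues, excluding any trailing stop marker."""
    seq = protein.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    return sum(1 for ch in seq if ch in _AA_INDEX)


def build_feature_vector(
    record,
    table: AdaptednessTable | None = None,
    code: int = DEFAULT_GENETIC_CODE,
) -> FeatureVector:
    """Assemble the 89-feature vector for one gene record.

    ``record`` needs ``gene_id``, ``dna`` and ``protein`` attributes.  When
    ``table`` is None the adaptedness reference is the gene's own codon
    counts (self-referential CAI, the default); pass a pooled per-species
    table for a shared reference.
    """
    rid = getattr(record, "gene_id", "<record>")
    try:
        counts = count_codons(record.dna, rid)
        ref_table = table if table is not None else relative_adaptedness(counts, code)
        values = np.concatenate(
            [
                codon_frequencies(counts),
                [
                    gc_content(record.dna, rid),
                    float(len(record.dna)),
                    cai(counts, ref_table),
                    rscu_max(rscu(counts, code)),
                ],
                aa_frequencies(record.protein, rid),
                [float(counted_protein_length(record.protein))],
            ]
        )
    except InvalidInputError as exc:
        raise InvalidInputError(f"{rid}: {exc}") from exc
    return FeatureVector(values)


def feature_table(
    records,
    reference: str = "self",
    code: int = DEFAULT_GENETIC_CODE,
):
    """Feature DataFrame for a corpus: metadata columns + 89 feature columns.

    ``reference='self'`` computes CAI against each gene's own codon usage;
    ``reference='species'`` pools codon counts per species into a shared
    adaptedness table.
    """
    import pandas as pd

    if reference not in ("self", "species"):
        raise ConfigurationError(f"unknown CAI reference mode: {reference!r}")
    species_tables: dict[str, AdaptednessTable] = {}
    if reference == "species":
        pooled: dict[str, CodonCounts] = {}
        for rec in records:
            c = count_codons(rec.dna, rec.gene_id)
            pooled[rec.species] = pooled[rec.species] + c if rec.species in pooled else c
        species_tables = {
            sp: relative_adaptedness(c, code) for sp, c in pooled.items()
        }
    rows = []
    for rec in records:
        table = species_tables.get(rec.species) if reference == "species" else None
        vec = build_feature_vector(rec, table, code)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "species": rec.species,
                "essential": int(rec.essential),
                "cluster_id": rec.cluster_id or "",
                **vec.as_dict(),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "species", "essential", "cluster_id", *FEATURE_NAMES])
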
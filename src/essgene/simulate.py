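"""Synthetic labeled gene corpora with the structure the classifier assumes.

The generator emulates what curated bacterial essential-gene corpora look
like from the point of view of this package's feature set:

* class-conditional codon usage — essential and non-essential genes draw
  codons from two distributions tilted apart by ``codon_bias_strength``;
* a GC-content gap — the non-essential distribution is re-weighted toward
  G/C-rich codons by ``gc_shift``;
* log-normal gene lengths per class (essential genes slightly longer by
  default, as in Gram-positive collections);
* valid coding sequences: ATG start, sense codons only, one stop, and the
  exact bacterial-table translation as the paired protein;
* orthologous families shared across species: an ancestor gene copied
  into >= 2 species with per-base, synonymous-position-biased mutations,
  sharing a cluster id and label — the raw material of the train/test
  data leak.

``family_label_noise`` makes a fraction of families carry a label opposite
to the class distribution their sequence was drawn from.  Such genes are
predictable only by recognizing the family itself, which a random split
rewards (near-identical orthologs on both sides of the split) and a
cluster-aware split does not — reproducing the direction of the leak
effect without any real corpus.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .corpus import ClusterMap, GeneRecord, write_cluster_map, write_fasta_pair
from .errors import InvalidInputError
from .features import DEFAULT_GENETIC_CODE, codon_to_aa

#: sense codons under the bacterial code, lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c, aa in sorted(codon_to_aa(DEFAULT_GENETIC_CODE).items()) if aa != "*"
)
STOP_CODONS: tuple[str, ...] = tuple(
    c for c, aa in sorted(codon_to_aa(DEFAULT_GENETIC_CODE).items()) if aa == "*"
)
_GC_FRACTION = np.array([sum(b in "GC" for b in c) / 3 for c in SENSE_CODONS])
_AA_MAP = codon_to_aa(DEFAULT_GENETIC_CODE)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the package's study conditions.

    ``codon_bias_strength`` is the standard deviation of a per-codon
    log-weight tilt applied to the essential class; 0 means identical
    codon usage.  ``gc_shift`` (log-weight per unit codon GC fraction)
    raises the non-essential class's GC content.  Lengths are log-normal
    in codon units and never below 30 codons.
    """

    n_species: int = 3
    genes_per_species: int = 2000
    essential_fraction: float = 0.3
    codon_bias_strength: float = 0.6
    gc_shift: float = 0.4
    length_log_mean_essential: float = 5.75
    length_log_mean_nonessential: float = 5.60
    length_log_sd: float = 0.35
    ortholog_family_rate: float = 0.2
    mutation_rate: float = 0.02
    family_label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.essential_fraction < 1:
            raise InvalidInputError("essential_fraction must be in (0,1)")
        if self.codon_bias_strength < 0:
            raise InvalidInputError("codon_bias_strength must be >= 0")
        for name in ("ortholog_family_rate", "family_label_noise"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidInputError(f"{name} must be in [0,1]")
        if not 0 <= self.mutation_rate < 1:
            raise InvalidInputError("mutation_rate must be in [0,1)")
        if self.n_species * self.genes_per_species <= 0:
            raise InvalidInputError("config implies an empty corpus")

    def null_signal(self) -> "SyntheticConfig":
        """The same corpus with every class-conditional difference removed."""
        return dataclasses.replace(
            self,
            codon_bias_strength=0.0,
            gc_shift=0.0,
            length_log_mean_essential=self.length_log_mean_nonessential,
        )


def sample_class_codon_distributions(config: SyntheticConfig):
    """Draw the (essential, non-essential) sense-codon distributions.

    A base distribution comes from a symmetric Dirichlet; the essential
    class is tilted in log space by ``codon_bias_strength`` and the
    non-essential class re-weighted toward GC-rich codons by ``gc_shift``.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    base = rng.dirichlet(np.full(len(SENSE_CODONS), 5.0))
    tilt = rng.standard_normal(len(SENSE_CODONS))
    essential = base * np.exp(config.codon_bias_strength * tilt)
    essential /= essential.sum()
    nonessential = base * np.exp(config.gc_shift * _GC_FRACTION)
    nonessential /= nonessential.sum()
    return essential, nonessential


def generate_gene(
    distribution: np.ndarray, length: int, rng: np.random.Generator
) -> tuple[str, str]:
    """One CDS of ``length`` codons (ATG + body + stop) and its protein."""
    if length < 2:
        raise InvalidInputError("gene length must be at least 2 codons")
    body = rng.choice(len(SENSE_CODONS), size=length - 2, p=distribution)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    dna = "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop
    protein = str(Seq(dna[:-3]).translate(table=DEFAULT_GENETIC_CODE))
    return dna, protein


def _mutate(dna: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base substitution, biased toward synonymous third positions.

    Third codon positions mutate at the full rate, first/second at a tenth
    of it; a substitution that would create a premature stop codon is
    skipped so the gene stays translatable.
    """
    if rate == 0:
        return dna
    bases = list(dna)
    aa_map = _AA_MAP
    for i in range(3, len(bases) - 3):  # preserve start and stop codons
        pos_rate = rate if i % 3 == 2 else rate / 10
        if rng.random() >= pos_rate:
            continue
        alternatives = [b for b in "ACGT" if b != bases[i]]
        new = alternatives[rng.integers(3)]
        codon_start = i - i % 3
        trial = bases[codon_start:codon_start + 3]
        trial[i % 3] = new
        if aa_map["".join(trial)] == "*":
            continue
        bases[i] = new
    return "".join(bases)


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[GeneRecord], ClusterMap]:
    """Generate the full labeled corpus plus its orthology cluster map.

    Family genes descend from a shared ancestor copied into >= 2 species
    (label preserved, per-base mutations applied); the remaining genes are
    independent singletons.  Species accessions are SYN_0001, SYN_0002, ...
    """
    rng = np.random.default_rng(config.seed)
    ess_dist, non_dist = sample_class_codon_distributions(config)
    dists = {True: ess_dist, False: non_dist}
    log_means = {
        True: config.length_log_mean_essential,
        False: config.length_log_mean_nonessential,
    }
    species = [f"SYN_{i + 1:04d}" for i in range(config.n_species)]
    slots = {sp: config.genes_per_species for sp in species}

    def draw_length(essential: bool) -> int:
        length = int(np.exp(rng.normal(log_means[essential], config.length_log_sd)))
        return max(length, 30)

    records: list[GeneRecord] = []
    assignments: dict[str, str] = {}
    counter = 0

    # orthologous families first (only possible with >= 2 species)
    n_total = config.n_species * config.genes_per_species
    n_family_genes = int(round(config.ortholog_family_rate * n_total))
    family_idx = 0
    while config.n_species >= 2 and sum(slots.values()) > n_total - n_family_genes:
        open_species = [sp for sp in species if slots[sp] > 0]
        if len(open_species) < 2:
            break
        essential = bool(rng.random() < config.essential_fraction)
        size = min(
            2 + int(rng.integers(config.n_species)), len(open_species)
        )
        members = [open_species[i] for i in rng.choice(len(open_species), size=size, replace=False)]
        # a noisy family's sequences come from the opposite class's codon pool
        noisy = bool(rng.random() < config.family_label_noise)
        dna, _ = generate_gene(dists[essential != noisy], draw_length(essential), rng)
        family_idx += 1
        cluster = f"fam{family_idx:05d}"
        for sp in members:
            mutated = _mutate(dna, config.mutation_rate, rng)
            protein = str(Seq(mutated[:-3]).translate(table=DEFAULT_GENETIC_CODE))
            counter += 1
            gene_id = f"{sp}_g{counter:06d}"
            records.append(
                GeneRecord(gene_id, sp, mutated, protein, essential, cluster)
            )
            assignments[gene_id] = cluster
            slots[sp] -= 1

    # independent singleton genes fill the remaining per-species slots
    for sp in species:
        for _ in range(slots[sp]):
            essential = bool(rng.random() < config.essential_fraction)
            dna, protein = generate_gene(
                dists[essential], draw_length(essential), rng
            )
            counter += 1
            gene_id = f"{sp}_g{counter:06d}"
            cluster = f"single:{gene_id}"
            records.append(
                GeneRecord(gene_id, sp, dna, protein, essential, cluster)
            )
            assignments[gene_id] = cluster

    if not records:
        raise InvalidInputError("configuration produced an empty corpus")
    return records, ClusterMap(assignments)


def leak_prone_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Study conditions for the data-leak experiment.

    Most genes belong to cross-species families, and a third of the
    families carry labels opposite to their codon profile, so family
    memorization — available only to random splits — pays off.
    """
    params = dict(
        ortholog_family_rate=0.6,
        family_label_noise=0.35,
        mutation_rate=0.01,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def write_corpus(
    records: list[GeneRecord],
    cmap: ClusterMap,
    config: SyntheticConfig,
    outdir: str | Path,
) -> list[Path]:
    """Write FASTA pairs per species/class, the cluster TSV and provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    by_group: dict[tuple[str, bool], list[GeneRecord]] = {}
    for rec in records:
        by_group.setdefault((rec.species, rec.essential), []).append(rec)
    for (sp, essential), group in sorted(by_group.items()):
        tag = "essential" if essential else "nonessential"
        dna_path = outdir / f"{sp}_{tag}.fna"
        prot_path = outdir / f"{sp}_{tag}.faa"
        write_fasta_pair(group, dna_path, prot_path)
        written += [dna_path, prot_path]
    cluster_path = outdir / "clusters.tsv"
    write_cluster_map(cmap, cluster_path)
    written.append(cluster_path)
    provenance = outdir / "provenance.json"
    provenance.write_text(
        json.dumps({"config": dataclasses.asdict(config)}, indent=2)
    )
    written.append(provenance)
    return written
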
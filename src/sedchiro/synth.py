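"""Synthetic references, assemblages and paired reads for pipeline testing.

The generator emulates the structure of a sediment-core CO1 metabarcoding
experiment: a reference set of species whose amplicon inserts are at
least 8% divergent from one another (the premise under which the short
fragment resolves species), an assemblage design of cores x layers in
which two littoral cores share most of their taxa while a deep core is
distinct, and paired 150 nt reads over the amplicons carrying per-base
quality-driven substitution errors, two-parent chimeras, stop-codon
numts, and database-absent contaminants.  A truth table records every
read's origin so downstream filters can be scored exactly.

All randomness flows from a single seed through per-stage child
generators; the same config yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .amplicon import QualityRead
from .refdb import IUPAC, PrimerSet, ReferenceRecord, revcomp, CH_PRIMERS
from .taxonomy import Lineage

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG"}  # stops of the invertebrate mitochondrial code


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults encode the emulated design: three cores with three layers
    each, the two shallow cores sharing ~0.8 of their taxa (Jaccard)
    against ~0.3 with the deep core, log-normal taxon abundances, a
    Q35-dominated quality profile and low rates of chimeric, numt and
    database-absent contaminant amplicons.
    """

    seed: int = 0
    n_species: int = 20
    n_genera: int = 8
    n_families: int = 1
    insert_len: int = 139
    min_interspecific_divergence: float = 0.08
    n_cores: int = 3
    n_layers: int = 3
    core_pool_size: int = 10
    shared_taxa_fractions: dict = field(
        default_factory=lambda: {"1-2": 0.8, "1-3": 0.3, "2-3": 0.3}
    )
    layer_retention: float = 0.9
    abundance_mu: float = 1.0
    abundance_sigma: float = 1.0
    reads_per_sample: int = 1500
    read_len: int = 150
    base_quality: int = 35
    dip_quality: int = 15
    dip_fraction: float = 0.01
    chimera_rate: float = 0.02
    numt_rate: float = 0.02
    contaminant_rate: float = 0.05
    n_contaminant_templates: int = 3
    pad_len: int = 30

    def validate(self, primers: PrimerSet, min_overlap: int = 50) -> None:
        for rate in (self.chimera_rate, self.numt_rate, self.contaminant_rate,
                     self.dip_fraction, self.layer_retention):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not self.n_species >= self.n_genera >= self.n_families >= 1:
            raise ValueError("need n_species >= n_genera >= n_families >= 1")
        amplicon_len = (
            self.insert_len + primers.forward.length + primers.reverse.length
        )
        if 2 * self.read_len - amplicon_len < min_overlap:
            raise ValueError(
                f"read_len {self.read_len} cannot give the minimum overlap of"
                f" {min_overlap} over a {amplicon_len} bp amplicon"
            )


@dataclass
class SimulatedReferences:
    """Reference records plus the ground-truth amplicon geometry."""

    records: list[ReferenceRecord]
    lineages: dict[str, Lineage]
    inserts: dict[str, str]      # species -> insert (primer-trimmed)
    amplicons: dict[str, str]    # species -> full amplicon incl. primers
    species: list[str]


def _expand_primer(primer_bases: str, rng: np.random.Generator) -> str:
    """One concrete expansion of a degenerate primer."""
    out = []
    for code in primer_bases:
        allowed = sorted(IUPAC[code])
        out.append(allowed[rng.integers(len(allowed))])
    return "".join(out)


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(_BASES[rng.integers(4, size=3)])
        if codon not in _STOPS:
            return codon


def _random_insert(length: int, rng: np.random.Generator) -> str:
    """Random stop-free (frame 0) insert of the requested length."""
    n_codons = length // 3
    seq = "".join(_random_codon(rng) for _ in range(n_codons))
    tail = length - 3 * n_codons
    if tail:
        seq += "".join(_BASES[rng.integers(4, size=tail)])
    return seq


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def simulate_references(
    config: SimulationConfig,
    primers: PrimerSet = CH_PRIMERS,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedReferences:
    """Generate species references satisfying the divergence premise.

    Every pair of species inserts differs at >= ceil(divergence *
    insert_len) sites (rejection sampling); full records are pad +
    concrete forward-primer expansion + insert + revcomp(concrete reverse
    expansion) + pad, with lineages nested into genera and families under
    a shared higher classification.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0]
        )
    min_sites = math.ceil(config.min_interspecific_divergence * config.insert_len)
    if min_sites > config.insert_len:
        raise ValueError("divergence requirement exceeds insert length")

    inserts: list[str] = []
    attempts = 0
    while len(inserts) < config.n_species:
        attempts += 1
        if attempts > 1000 * config.n_species:
            raise ValueError(
                "cannot satisfy divergence constraint for this configuration"
            )
        cand = _random_insert(config.insert_len, rng)
        if all(_hamming(cand, other) >= min_sites for other in inserts):
            inserts.append(cand)

    genus_of_species = [i % config.n_genera for i in range(config.n_species)]
    family_of_genus = [g % config.n_families for g in range(config.n_genera)]

    records, lineages = [], {}
    insert_of, amplicon_of = {}, {}
    species_names = []
    for i, insert in enumerate(inserts):
        genus = f"Genus{genus_of_species[i] + 1}"
        family = (
            "Chironomidae"
            if family_of_genus[genus_of_species[i]] == 0
            else f"Family{family_of_genus[genus_of_species[i]] + 1}"
        )
        species = f"{genus} species{i + 1}"
        seq_id = f"ref_{i + 1}"
        fwd = _expand_primer(primers.forward.bases, rng)
        rev = _expand_primer(primers.reverse.bases, rng)
        pad5 = "".join(_BASES[rng.integers(4, size=config.pad_len)])
        pad3 = "".join(_BASES[rng.integers(4, size=config.pad_len)])
        amplicon = fwd + insert + revcomp(rev)
        lineage = Lineage.of(
            source_id=seq_id,
            kingdom="Animalia",
            phylum="Arthropoda",
            **{"class": "Insecta"},
            order="Diptera",
            family=family,
            genus=genus,
            species=species,
        )
        records.append(
            ReferenceRecord(seq_id, pad5 + amplicon + pad3, lineage, source="synthetic")
        )
        lineages[seq_id] = lineage
        insert_of[species] = insert
        amplicon_of[species] = amplicon
        species_names.append(species)
    return SimulatedReferences(records, lineages, insert_of, amplicon_of, species_names)


def _overlap_count(n: int, jaccard: float) -> int:
    """Members shared by two size-n pools to hit a target Jaccard index."""
    return int(round(2 * n * jaccard / (1 + jaccard)))


def simulate_assemblages(
    config: SimulationConfig,
    species: list[str],
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-sample true taxon abundances honoring the shared-taxa design.

    Cores draw species pools whose pairwise Jaccard overlap matches
    ``shared_taxa_fractions``; layers subsample their core's pool
    independently (retention probability per taxon) with log-normal
    abundances.  Returns a samples x species table of abundance weights;
    sample ids are ``SS<core>_L<layer>``.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(2)[1]
        )
    n = config.core_pool_size
    if n > len(species):
        raise ValueError("core_pool_size exceeds species pool")
    frac = {
        tuple(sorted(int(x) for x in k.split("-"))): v
        for k, v in config.shared_taxa_fractions.items()
    }
    available = list(species)
    rng.shuffle(available)
    pools: list[list[str]] = []

    def take(k: int) -> list[str]:
        if k > len(available):
            raise ValueError("shared-taxa design needs more species")
        out = available[:k]
        del available[:k]
        return out

    if config.n_cores >= 2:
        s12 = frac.get((1, 2), 0.5)
        o12 = min(_overlap_count(n, s12), n)
        shared12 = take(o12)
        pools.append(shared12 + take(n - o12))
        pools.append(shared12 + take(n - o12))
        for c in range(3, config.n_cores + 1):
            s1c = frac.get((1, c), 0.3)
            s2c = frac.get((2, c), s1c)
            oc = min(_overlap_count(n, (s1c + s2c) / 2.0), len(shared12))
            shared_c = list(shared12[:oc])
            pools.append(shared_c + take(n - len(shared_c)))
    else:
        pools.append(take(n))

    samples, rows = [], []
    for c, pool in enumerate(pools, start=1):
        for layer in range(1, config.n_layers + 1):
            present = [
                sp for sp in pool if rng.random() < config.layer_retention
            ]
            if not present:  # a layer always holds at least one taxon
                present = [pool[int(rng.integers(len(pool)))]]
            weights = {
                sp: float(
                    rng.lognormal(config.abundance_mu, config.abundance_sigma)
                )
                for sp in present
            }
            samples.append(f"SS{c}_L{layer}")
            rows.append(weights)
    table = pd.DataFrame(rows, index=samples, columns=species).fillna(0.0)
    return table


@dataclass
class SimulatedReads:
    """Paired reads per sample plus the per-read origin truth table."""

    pairs: dict[str, list[tuple[QualityRead, QualityRead]]]
    truth: pd.DataFrame
    contaminant_templates: list[str]


def _mutate_with_quality(
    seq: str,
    rng: np.random.Generator,
    base_q: int,
    dip_q: int,
    dip_fraction: float,
) -> tuple[str, np.ndarray]:
    n = len(seq)
    quals = np.full(n, base_q, dtype=np.int16)
    dips = rng.random(n) < dip_fraction
    quals[dips] = dip_q
    p_err = 10.0 ** (-quals / 10.0)
    errors = rng.random(n) < p_err
    if not errors.any():
        return seq, quals
    arr = np.array(list(seq))
    for i in np.nonzero(errors)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr), quals


def _numt_template(amplicon: str, primers: PrimerSet, insert_len: int) -> str:
    """Inject a premature stop codon (>= 2 substitutions) into the insert."""
    flen = primers.forward.length
    for j in range(2, insert_len // 3 - 1):
        start = flen + 3 * j
        codon = amplicon[start : start + 3]
        if codon not in _STOPS and _hamming(codon, "TAA") >= 2:
            return amplicon[:start] + "TAA" + amplicon[start + 3 :]
    # fallback: any non-stop codon position
    for j in range(2, insert_len // 3 - 1):
        start = flen + 3 * j
        if amplicon[start : start + 3] not in _STOPS:
            return amplicon[:start] + "TAA" + amplicon[start + 3 :]
    raise ValueError("no codon available for numt injection")


def simulate_reads(
    assemblage: pd.DataFrame,
    references: SimulatedReferences,
    config: SimulationConfig,
    primers: PrimerSet = CH_PRIMERS,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedReads:
    """Emit paired FASTQ-style reads with errors, chimeras, numts and
    contaminants, and a truth table of every read's origin class."""
    config.validate(primers)
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(3)[2]
        )

    # contaminant templates: random inserts far from every reference
    contaminants: list[str] = []
    ref_inserts = list(references.inserts.values())
    guard = 0
    while len(contaminants) < config.n_contaminant_templates:
        guard += 1
        if guard > 1000:
            raise ValueError("cannot draw contaminants below 85% identity")
        cand = _random_insert(config.insert_len, rng)
        identities = [
            100.0 * (1 - _hamming(cand, r) / config.insert_len) for r in ref_inserts
        ]
        if max(identities, default=0.0) < 85.0:
            fwd = _expand_primer(primers.forward.bases, rng)
            rev = _expand_primer(primers.reverse.bases, rng)
            contaminants.append(fwd + cand + revcomp(rev))

    numt_of = {
        sp: _numt_template(amp, primers, config.insert_len)
        for sp, amp in references.amplicons.items()
    }

    flen = primers.forward.length
    pairs: dict[str, list[tuple[QualityRead, QualityRead]]] = {}
    truth_rows = []
    for sample in assemblage.index:
        weights = assemblage.loc[sample].values.astype(float)
        if weights.sum() <= 0:
            raise ValueError(f"sample {sample} has no taxa")
        probs = weights / weights.sum()
        taxa = list(assemblage.columns)
        counts = rng.multinomial(config.reads_per_sample, probs)
        sample_pairs: list[tuple[QualityRead, QualityRead]] = []
        read_no = 0
        for t_idx, n_reads in enumerate(counts):
            for _ in range(int(n_reads)):
                read_no += 1
                read_id = f"{sample}_r{read_no}"
                u = rng.random()
                taxon = taxa[t_idx]
                if u < config.chimera_rate:
                    other = int(rng.choice(len(taxa), p=probs))
                    if other == t_idx:
                        other = (t_idx + 1) % len(taxa)
                    amp_a = references.amplicons.get(taxon)
                    amp_b = references.amplicons[taxa[other]]
                    k = int(
                        rng.integers(flen + 1, flen + config.insert_len - 1)
                    )
                    template = amp_a[:k] + amp_b[k:]
                    origin, origin_taxon = "chimera", f"{taxon}+{taxa[other]}"
                elif u < config.chimera_rate + config.numt_rate:
                    template = numt_of[taxon]
                    origin, origin_taxon = "numt", taxon
                elif u < config.chimera_rate + config.numt_rate + config.contaminant_rate:
                    c = int(rng.integers(len(contaminants)))
                    template = contaminants[c]
                    origin, origin_taxon = "contaminant", f"contaminant_{c + 1}"
                else:
                    template = references.amplicons[taxon]
                    origin, origin_taxon = "normal", taxon

                r1_seq = template[: config.read_len]
                r2_seq = revcomp(template)[: config.read_len]
                r1_seq, q1 = _mutate_with_quality(
                    r1_seq, rng, config.base_quality, config.dip_quality,
                    config.dip_fraction,
                )
                r2_seq, q2 = _mutate_with_quality(
                    r2_seq, rng, config.base_quality, config.dip_quality,
                    config.dip_fraction,
                )
                sample_pairs.append(
                    (
                        QualityRead(read_id, r1_seq, q1, sample=sample),
                        QualityRead(read_id, r2_seq, q2, sample=sample),
                    )
                )
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "sample": sample,
                        "origin": origin,
                        "taxon": origin_taxon,
                    }
                )
        pairs[sample] = sample_pairs
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample", "origin", "taxon"]
    )
    return SimulatedReads(pairs, truth, contaminants)


@dataclass
class SimulationBundle:
    config: SimulationConfig
    references: SimulatedReferences
    assemblage: pd.DataFrame
    reads: SimulatedReads


def simulate_all(
    config: SimulationConfig, primers: PrimerSet = CH_PRIMERS
) -> SimulationBundle:
    """References + assemblages + reads from one seed, deterministically."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    refs = simulate_references(
        config, primers, rng=np.random.default_rng(children[0])
    )
    assemblage = simulate_assemblages(
        config, refs.species, rng=np.random.default_rng(children[1])
    )
    reads = simulate_reads(
        assemblage, refs, config, primers, rng=np.random.default_rng(children[2])
    )
    return SimulationBundle(config, refs, assemblage, reads)
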
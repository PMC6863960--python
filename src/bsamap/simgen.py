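"""Synthetic F2 population and pooled-sequencing generator for BSA-seq.

Emulates the data structure of a bulked-segregant experiment on a single
fully penetrant recessive locus: an F2 population from a cross between a
normal-height and a dwarf inbred line, two bulks of phenotypic extremes,
and per-site bulk allele read counts as produced by whole-genome
re-sequencing of the pooled DNA (Poisson total depth, binomial allele
sampling from the bulk allele frequency, symmetric sequencing error).

Meiosis follows the no-interference (Haldane) model: crossover counts per
chromosome are Poisson with mean equal to the chromosome's map length in
Morgans and breakpoints are uniform on the genetic map.  The population
simulator uses the equivalent Markov-chain formulation (independent
switch events between adjacent markers with probability given by the
Haldane map function), which is exact under no interference and
vectorizes over gametes.  Linkage *estimation* elsewhere in the package
uses the Kosambi function; at the short distances relevant for fine
mapping the two differ negligibly.

Only biallelic sites at which the two parents are fixed for opposite
alleles are emitted — the informative-SNP set that survives a parental
comparison.  By default the reference allele is the normal-parent allele
(the assembly-vs-parents relation is unknowable in general; a polarity
flag randomizes it per site).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .linkmap import haldane_inverse

__all__ = [
    "SimConfig",
    "F2Cohort",
    "VARIANT_COLUMNS",
    "build_marker_map",
    "simulate_gamete",
    "simulate_f2",
    "make_bulks",
    "simulate_bulk_counts",
    "simulate_experiment",
]

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "parent_hi", "parent_dw",
    "d_ref", "d_alt", "n_ref", "n_alt",
]

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the default simulation.

    Defaults mirror the experiment the package emulates: an 11-chromosome
    genome, a single recessive dwarfing locus near the distal end of
    chromosome 9, 20 + 20 plant bulks sequenced to an average 34x depth.
    Chromosome size (~34 Mb) and map length (120 cM) are typical for a
    watermelon chromosome; 200 informative markers per chromosome is a
    deliberately sparse stand-in for a filtered whole-genome SNP set.
    """

    n_chromosomes: int = 11
    chrom_length_bp: int = 34_000_000
    map_length_morgans: float = 1.2
    n_markers_per_chrom: int = 200
    causal_chrom: str = "chr9"
    causal_pos_bp: int = 30_400_000
    n_f2: int = 500
    bulk_size: int = 20
    mean_depth: float = 34.0
    seq_error: float = 0.001
    rng_seed: int = 1
    randomize_polarity: bool = False
    null_locus: bool = False  # True: phenotype independent of genotype (no causal locus)

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_markers_per_chrom < 1:
            raise ValueError("need at least one chromosome and one marker per chromosome")
        if not (0 <= self.seq_error < 0.5):
            raise ValueError(f"seq_error must be in [0, 0.5), got {self.seq_error}")
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be > 0, got {self.mean_depth}")
        if self.map_length_morgans < 0:
            raise ValueError("map_length_morgans must be >= 0")
        if not (1 <= self.causal_pos_bp <= self.chrom_length_bp):
            raise ValueError(
                f"causal_pos_bp {self.causal_pos_bp} outside [1, {self.chrom_length_bp}]"
            )
        if self.causal_chrom not in self.chromosomes:
            raise ValueError(f"causal_chrom {self.causal_chrom!r} not in {self.chromosomes}")
        if self.n_f2 < 1 or self.bulk_size < 0:
            raise ValueError("n_f2 must be >= 1 and bulk_size >= 0")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes + 1)]


@dataclass
class F2Cohort:
    """A simulated (or ingested) F2 population.

    genotypes[i, j] is the dosage (0/1/2) of the dwarf-parent (B) allele
    of individual i at marker j; haplotypes[i, k, j] records which
    parental chromosome (0 = normal parent, 1 = dwarf parent) gamete k of
    individual i carries at marker j, and is retained so that tests can
    recount recombination events directly.
    """

    ids: list[str]
    genotypes: np.ndarray          # (n, m) int8 dosage of the B allele
    phenotypes: np.ndarray         # (n,) bool, True = dwarf
    marker_map: pd.DataFrame       # columns marker, chrom, pos_bp, pos_cm
    causal_index: int
    haplotypes: np.ndarray | None = None  # (n, 2, m) uint8
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if len(self.ids) != n or len(self.phenotypes) != n:
            raise ValueError("ids/phenotypes length does not match genotypes")
        if len(self.marker_map) != m:
            raise ValueError("marker map length does not match genotype columns")
        if not (0 <= self.causal_index < m):
            raise ValueError("causal_index out of range")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def genotype_codes(self) -> np.ndarray:
        """Genotypes as AA/AB/BB strings (A = normal-parent allele)."""
        return np.array(["AA", "AB", "BB"])[self.genotypes]


def build_marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Random marker positions, always including the causal site itself.

    Genetic positions assume a uniform recombination rate along each
    chromosome: pos_cm = pos_bp / chrom_length_bp * 100 * map_length_M.
    """
    rows = []
    for chrom in config.chromosomes:
        # rejection sampling of distinct positions (collision odds are tiny
        # for realistic marker counts; avoids materializing the bp range)
        pos: set[int] = set()
        while len(pos) < config.n_markers_per_chrom:
            need = config.n_markers_per_chrom - len(pos)
            pos.update(
                int(p) for p in rng.integers(1, config.chrom_length_bp + 1, size=need)
            )
        if chrom == config.causal_chrom:
            pos.add(config.causal_pos_bp)
        for p in sorted(pos):
            rows.append((chrom, p))
    df = pd.DataFrame(rows, columns=["chrom", "pos_bp"])
    df["pos_cm"] = df["pos_bp"] / config.chrom_length_bp * config.map_length_morgans * 100.0
    df.insert(0, "marker", [f"{c}_{p}" for c, p in zip(df["chrom"], df["pos_bp"])])
    return df


def simulate_gamete(
    parent_phase: tuple[np.ndarray, np.ndarray],
    pos_cm: Sequence[float],
    map_length_morgans: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a pair of parental haplotypes.

    Crossover count is Poisson(map length in Morgans), breakpoints are
    uniform on the genetic map; no interference, no obligate chiasma.
    """
    hap0, hap1 = (np.asarray(h) for h in parent_phase)
    pos = np.asarray(pos_cm, dtype=float)
    if pos.size == 0:
        raise ValueError("empty marker map")
    if hap0.shape != pos.shape or hap1.shape != pos.shape:
        raise ValueError("haplotype length does not match marker map")
    if np.any(np.diff(pos) < 0):
        raise ValueError("marker positions must be sorted within the chromosome")
    n_xo = rng.poisson(map_length_morgans)
    breaks = np.sort(rng.uniform(0.0, map_length_morgans * 100.0, size=n_xo))
    start = rng.integers(2)
    # haplotype index at each marker: parity of crossovers to its left
    which = (start + np.searchsorted(breaks, pos, side="right")) % 2
    return np.where(which == 0, hap0, hap1)


def _gametes_markov(
    n_gametes: int, pos_cm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n_gametes, m) parental-origin indicators under the Haldane model."""
    m = pos_cm.size
    out = np.empty((n_gametes, m), dtype=np.uint8)
    out[:, 0] = rng.integers(2, size=n_gametes, dtype=np.uint8)
    if m > 1:
        r = np.array([haldane_inverse(d) for d in np.diff(pos_cm)])
        switches = rng.random((n_gametes, m - 1)) < r
        np.logical_xor.accumulate(switches, axis=1, out=switches)
        out[:, 1:] = out[:, :1] ^ switches.astype(np.uint8)
    return out


def simulate_f2(config: SimConfig, rng: np.random.Generator | None = None) -> F2Cohort:
    """Simulate an F2 population from two independent gametes per individual.

    The F1 is heterozygous everywhere (inbred parents fixed for opposite
    alleles), so a gamete is fully described by which parental chromosome
    it carries at each marker.  Phenotype is dwarf iff the individual is
    homozygous for the dwarf-parent allele at the causal locus.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    marker_map = build_marker_map(config, rng)
    n, m = config.n_f2, len(marker_map)
    haplotypes = np.empty((n, 2, m), dtype=np.uint8)
    for chrom, sub in marker_map.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        gametes = _gametes_markov(2 * n, sub["pos_cm"].to_numpy(), rng)
        haplotypes[:, 0, idx[0]:idx[-1] + 1] = gametes[:n]
        haplotypes[:, 1, idx[0]:idx[-1] + 1] = gametes[n:]
    genotypes = haplotypes.sum(axis=1).astype(np.int8)
    causal_index = int(np.flatnonzero(
        (marker_map["chrom"] == config.causal_chrom)
        & (marker_map["pos_bp"] == config.causal_pos_bp)
    )[0])
    if config.null_locus:
        # null model: dwarf phenotype assigned at the 1/4 Mendelian rate but
        # independently of any genotype (no causal locus anywhere)
        phenotypes = rng.random(n) < 0.25
    else:
        phenotypes = genotypes[:, causal_index] == 2
    ids = [f"F2_{i + 1:04d}" for i in range(n)]
    return F2Cohort(
        ids=ids, genotypes=genotypes, phenotypes=phenotypes,
        marker_map=marker_map, causal_index=causal_index,
        haplotypes=haplotypes, config=config,
    )


def make_bulks(
    cohort: F2Cohort, bulk_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample bulk members (row indices) without replacement per phenotype class."""
    dwarf_idx = np.flatnonzero(cohort.phenotypes)
    normal_idx = np.flatnonzero(~cohort.phenotypes)
    for name, pool in (("dwarf", dwarf_idx), ("normal", normal_idx)):
        if len(pool) < bulk_size:
            raise ValueError(
                f"{name} class has {len(pool)} individuals, fewer than bulk_size={bulk_size}"
            )
    dwarf_bulk = np.sort(rng.choice(dwarf_idx, size=bulk_size, replace=False))
    normal_bulk = np.sort(rng.choice(normal_idx, size=bulk_size, replace=False))
    return dwarf_bulk, normal_bulk


def simulate_bulk_counts(
    cohort: F2Cohort,
    bulks: tuple[np.ndarray, np.ndarray],
    mean_depth: float,
    seq_error: float,
    rng: np.random.Generator,
    randomize_polarity: bool = False,
) -> pd.DataFrame:
    """Per-site bulk allele read counts (one VariantSite row per marker).

    Each bulk's true alt-allele frequency at a site is the unweighted
    mean of its members' dosages / 2 (equal DNA per plant).  Total depth
    per site per bulk is Poisson(mean_depth); each read reports the true
    allele flipped with probability seq_error (symmetric ref<->alt).
    The alt allele is the dwarf-parent allele unless polarity is
    randomized, in which case ref/alt labels are swapped per site with
    probability 1/2 (parental columns track the swap).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    dwarf_bulk, normal_bulk = bulks
    m = cohort.n_markers
    freqs = {}
    counts = {}
    for key, members in (("d", dwarf_bulk), ("n", normal_bulk)):
        if len(members):
            f = cohort.genotypes[members].mean(axis=0) / 2.0
        else:
            f = np.zeros(m)
        p_alt_read = f * (1.0 - seq_error) + (1.0 - f) * seq_error
        total = rng.poisson(mean_depth, size=m)
        alt = rng.binomial(total, p_alt_read)
        freqs[key] = f
        counts[key] = (total - alt, alt)

    ref_base = rng.integers(4, size=m)
    alt_base = (ref_base + rng.integers(1, 4, size=m)) % 4
    ref, alt = _NUCS[ref_base], _NUCS[alt_base]

    df = pd.DataFrame({
        "chrom": cohort.marker_map["chrom"].to_numpy(),
        "pos": cohort.marker_map["pos_bp"].to_numpy(),
        "ref": ref, "alt": alt,
        "parent_hi": ref, "parent_dw": alt,
        "d_ref": counts["d"][0], "d_alt": counts["d"][1],
        "n_ref": counts["n"][0], "n_alt": counts["n"][1],
    })
    if randomize_polarity:
        swap = rng.random(m) < 0.5
        for a, b in (("ref", "alt"), ("d_ref", "d_alt"), ("n_ref", "n_alt")):
            df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
        # after a swap the dwarf-parent allele is the (new) ref
        df.loc[swap, "parent_hi"] = df.loc[swap, "alt"]
        df.loc[swap, "parent_dw"] = df.loc[swap, "ref"]
    return df


def simulate_experiment(
    config: SimConfig,
) -> tuple[F2Cohort, tuple[np.ndarray, np.ndarray], pd.DataFrame]:
    """Full generative run: cohort, bulks, and bulk-sequencing variant table."""
    rng = np.random.default_rng(config.rng_seed)
    cohort = simulate_f2(config, rng)
    bulks = make_bulks(cohort, config.bulk_size, rng)
    sites = simulate_bulk_counts(
        cohort, bulks, config.mean_depth, config.seq_error, rng,
        randomize_polarity=config.randomize_polarity,
    )
    return cohort, bulks, sites
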
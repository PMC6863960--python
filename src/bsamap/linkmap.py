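"""Segregation testing and two-point linkage mapping for F2 populations.

Implements the classical genetics layer of a map-based cloning project:

* chi-square goodness-of-fit against a Mendelian segregation ratio
  (Yates-corrected by default for 1-df tables),
* maximum-likelihood recombination fractions between codominant markers
  (EM over the nine two-locus F2 classes) and between a fully penetrant
  recessive trait locus and a codominant marker (unambiguous-class
  recombinant counting, with a full-likelihood alternative),
* LOD scores against free recombination (r = 0.5),
* the Kosambi and Haldane map functions and their inverses,
* assembly of a cumulative genetic map along a given physical marker
  order, with trait placement, and physical interval arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SegregationTest",
    "LinkageEstimate",
    "chi2_segregation",
    "kosambi",
    "kosambi_inverse",
    "haldane",
    "haldane_inverse",
    "estimate_r_codominant",
    "estimate_r_trait",
    "lod_score",
    "assemble_map",
    "interval_span_kb",
    "genotype_counts",
    "f2_class_probs",
]

GENO_CODES = {"AA": 0, "AB": 1, "BA": 1, "BB": 2}


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi(r: float) -> float:
    """Kosambi map distance in cM for recombination fraction ``r``.

    d = 25 * ln((1 + 2r) / (1 - 2r)).  Returns ``inf`` for r >= 0.5
    (unlinked loci are at infinite map distance).
    """
    if r < 0:
        raise ValueError(f"recombination fraction must be >= 0, got {r}")
    if r >= 0.5:
        return math.inf
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(d_cm: float) -> float:
    """Recombination fraction for a Kosambi distance in cM."""
    if d_cm < 0:
        raise ValueError(f"map distance must be >= 0, got {d_cm}")
    if math.isinf(d_cm):
        return 0.5
    # d = 25 ln((1+2r)/(1-2r))  =>  r = tanh(d/50) / 2
    return 0.5 * math.tanh(d_cm / 50.0)


def haldane(r: float) -> float:
    """Haldane map distance in cM (no interference): d = -50 ln(1 - 2r)."""
    if r < 0:
        raise ValueError(f"recombination fraction must be >= 0, got {r}")
    if r >= 0.5:
        return math.inf
    return -50.0 * math.log(1.0 - 2.0 * r)


def haldane_inverse(d_cm: float) -> float:
    """Recombination fraction for a Haldane distance in cM."""
    if d_cm < 0:
        raise ValueError(f"map distance must be >= 0, got {d_cm}")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


# ---------------------------------------------------------------------------
# segregation chi-square
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegregationTest:
    """Result of a goodness-of-fit test against a Mendelian ratio."""

    n_total: int
    n_dominant: int
    n_recessive: int
    ratio: tuple[float, float]  # dominant : recessive
    chi2: float
    df: int
    p: float
    yates: bool


def chi2_segregation(
    n_dominant: int,
    n_recessive: int,
    ratio: tuple[float, float] = (3.0, 1.0),
    yates: bool = True,
) -> SegregationTest:
    """Chi-square goodness-of-fit of observed phenotype counts to a ratio.

    With ``yates`` (default, appropriate for the 1-df two-class table) the
    statistic is sum((|obs - exp| - 0.5)^2 / exp); the continuity
    correction never exceeds the deviation (clamped at 0).
    """
    if n_dominant < 0 or n_recessive < 0:
        raise ValueError("counts must be non-negative")
    if ratio[0] <= 0 or ratio[1] <= 0:
        raise ValueError("expected ratio classes must be positive")
    n = n_dominant + n_recessive
    if n == 0:
        raise ValueError("no observations")
    total_ratio = ratio[0] + ratio[1]
    expected = (n * ratio[0] / total_ratio, n * ratio[1] / total_ratio)
    if min(expected) == 0:
        raise ValueError("zero expected count")
    c = 0.5 if yates else 0.0
    chi2 = 0.0
    for obs, exp in zip((n_dominant, n_recessive), expected):
        dev = max(abs(obs - exp) - c, 0.0)
        chi2 += dev * dev / exp
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationTest(
        n_total=n, n_dominant=n_dominant, n_recessive=n_recessive,
        ratio=(float(ratio[0]), float(ratio[1])),
        chi2=chi2, df=1, p=p, yates=yates,
    )


# ---------------------------------------------------------------------------
# two-point linkage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkageEstimate:
    """Two-point linkage between two markers or a trait and a marker."""

    pair: tuple[str, str]
    r_hat: float
    lod: float
    d_kosambi_cm: float
    n_informative: int
    n_recombinant_events: float
    n_recombinant_individuals: int | None = None


def _to_dosage(genotypes: Sequence) -> np.ndarray:
    """Accept AA/AB/BB strings or 0/1/2 dosages of the B allele."""
    arr = np.asarray(genotypes)
    if arr.dtype.kind in "UO S".replace(" ", ""):
        try:
            return np.array([GENO_CODES[str(g)] for g in arr], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message clarity
            raise ValueError(f"unrecognized genotype code {exc}") from exc
    arr = arr.astype(np.int64)
    if arr.size and (arr.min() < 0 or arr.max() > 2):
        raise ValueError("dosages must be in {0, 1, 2}")
    return arr


def genotype_counts(g1: Sequence, g2: Sequence) -> np.ndarray:
    """3x3 table of joint genotype counts (rows locus 1, cols locus 2)."""
    d1, d2 = _to_dosage(g1), _to_dosage(g2)
    if d1.shape != d2.shape:
        raise ValueError("genotype vectors differ in length")
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (d1, d2), 1)
    return counts


def f2_class_probs(r: float) -> np.ndarray:
    """Probabilities of the nine F2 two-locus genotype classes (coupling).

    Gamete frequencies under no selection: parental (1-r)/2 each,
    recombinant r/2 each; individuals are products of two independent
    gametes, so the double heterozygote pools both phase configurations.
    """
    p = (1.0 - r) / 2.0  # parental gametes: (0,0), (1,1)
    q = r / 2.0          # recombinant gametes: (0,1), (1,0)
    probs = np.array([
        [p * p, 2 * p * q, q * q],
        [2 * p * q, 2 * (p * p + q * q), 2 * p * q],
        [q * q, 2 * p * q, p * p],
    ])
    return probs


# expected recombinant gametes contributed by each fully classified class;
# the double heterozygote (1,1) is latent and handled in the E-step
_REC_GAMETES = np.array([
    [0, 1, 2],
    [1, np.nan, 1],
    [2, 1, 0],
])


def _em_r(counts: np.ndarray, tol: float = 1e-12, max_iter: int = 500) -> tuple[float, float]:
    """EM estimate of r from a 3x3 F2 class table.

    Returns (r_hat, expected recombinant gamete count at r_hat).
    """
    n = counts.sum()
    n11 = counts[1, 1]
    known = np.nansum(_REC_GAMETES * counts)
    r = 0.25
    rec = known
    for _ in range(max_iter):
        if n11:
            # phase-latent double hets: P(repulsion | class) = r^2/(r^2+(1-r)^2)
            w = r * r / (r * r + (1.0 - r) * (1.0 - r))
            rec = known + 2.0 * w * n11
        else:
            rec = known
        r_new = rec / (2.0 * n)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return float(np.clip(r, 0.0, 0.5)), float(rec)


def _loglik_codominant(counts: np.ndarray, r: float) -> float:
    probs = f2_class_probs(r)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        ll = np.where(mask, counts * np.log(np.clip(probs, 1e-300, None)), 0.0)
    return float(ll.sum())


def estimate_r_codominant(
    g1: Sequence,
    g2: Sequence,
    pair: tuple[str, str] = ("m1", "m2"),
) -> LinkageEstimate:
    """ML recombination fraction between two codominant markers in an F2.

    Phase is known from the parents (coupling); the nine joint genotype
    classes are fully informative except the double heterozygote, whose
    two phase configurations are resolved fractionally by EM.
    """
    counts = genotype_counts(g1, g2)
    n = int(counts.sum())
    if n < 2:
        raise ValueError("need at least 2 informative individuals")
    r_hat, rec = _em_r(counts)
    lod = (_loglik_codominant(counts, r_hat) - _loglik_codominant(counts, 0.5)) / math.log(10.0)
    lod = max(lod, 0.0)
    return LinkageEstimate(
        pair=pair, r_hat=r_hat, lod=lod,
        d_kosambi_cm=kosambi(r_hat) if r_hat < 0.5 else math.inf,
        n_informative=n, n_recombinant_events=rec,
    )


def _trait_class_probs(r: float) -> tuple[np.ndarray, np.ndarray]:
    """P(marker dosage | dwarf) and P(marker dosage | normal) at distance r.

    Dwarf individuals are dd at the causal locus, so each of their two
    chromosomes carries the dwarf-parent marker allele w.p. 1 - r.
    Normal individuals are the 1 DD : 2 Dd remainder.
    """
    b = np.array([r * r, 2 * r * (1 - r), (1 - r) * (1 - r)])  # Binom(2, 1-r)
    q = np.array([0.25, 0.5, 0.25])
    p_dwarf = b
    p_normal = (q - 0.25 * b) / 0.75
    return p_dwarf, p_normal


def _loglik_trait(dwarf_counts: np.ndarray, normal_counts: np.ndarray, r: float) -> float:
    pd, pn = _trait_class_probs(r)
    pd = np.clip(pd, 1e-300, None)
    pn = np.clip(pn, 1e-300, None)
    return float((dwarf_counts * np.log(pd)).sum() + (normal_counts * np.log(pn)).sum())


def estimate_r_trait(
    phenotypes: Sequence,
    genotypes: Sequence,
    pair: tuple[str, str] = ("trait", "marker"),
    method: str = "count",
) -> LinkageEstimate:
    """Recombination fraction between a recessive trait and a codominant marker.

    ``method='count'`` (default) counts recombinant chromosomes from
    unambiguous classes only — the fine-mapping bookkeeping of scoring
    "recombinants" among genotyped plants:

    * dwarf (dd) individuals heterozygous at the marker: 1 event,
      homozygous for the normal-parent allele: 2 events;
    * normal individuals homozygous for the dwarf-parent marker allele:
      1 event (at least one recombinant chromosome, counted once);
    * other normal individuals are phase/genotype-ambiguous (DD vs Dd)
      and excluded from the denominator.

    r_hat = events / (2 * n_dwarf + n_informative_normals).

    ``method='ml'`` maximizes the full mixture likelihood over all
    individuals instead.  LOD is always computed from the full likelihood
    at the reported r_hat versus r = 0.5.
    """
    pheno = np.asarray(phenotypes)
    if pheno.dtype.kind in "UO":
        dwarf = np.array([str(x).lower() in ("dwarf", "d", "1", "true") for x in pheno])
    else:
        dwarf = pheno.astype(bool)
    dose = _to_dosage(genotypes)
    if dwarf.shape != dose.shape:
        raise ValueError("phenotype and genotype vectors differ in length")
    n_dwarf = int(dwarf.sum())
    if n_dwarf == 0:
        raise ValueError("no dwarf (recessive) individuals; trait r is inestimable")

    dwarf_counts = np.bincount(dose[dwarf], minlength=3)
    normal_counts = np.bincount(dose[~dwarf], minlength=3)

    # unambiguous recombination events
    events = dwarf_counts[1] * 1 + dwarf_counts[0] * 2 + normal_counts[2] * 1
    n_rec_ind = int(dwarf_counts[1] + dwarf_counts[0] + normal_counts[2])
    denom = 2 * n_dwarf + int(normal_counts[2])

    if method == "count":
        r_hat = float(np.clip(events / denom, 0.0, 0.5))
    elif method == "ml":
        res = optimize.minimize_scalar(
            lambda r: -_loglik_trait(dwarf_counts, normal_counts, r),
            bounds=(0.0, 0.5), method="bounded",
            options={"xatol": 1e-10},
        )
        r_hat = float(res.x)
    else:
        raise ValueError(f"unknown method {method!r}")

    lod = (_loglik_trait(dwarf_counts, normal_counts, r_hat)
           - _loglik_trait(dwarf_counts, normal_counts, 0.5)) / math.log(10.0)
    return LinkageEstimate(
        pair=pair, r_hat=r_hat, lod=max(lod, 0.0),
        d_kosambi_cm=kosambi(r_hat) if r_hat < 0.5 else math.inf,
        n_informative=n_dwarf + int(normal_counts[2]) + int(normal_counts[0] + normal_counts[1]),
        n_recombinant_events=float(events),
        n_recombinant_individuals=n_rec_ind,
    )


def lod_score(counts: np.ndarray, r_hat: float) -> float:
    """LOD = log10 L(r_hat)/L(0.5) for a 3x3 F2 two-locus class table."""
    counts = np.asarray(counts)
    if counts.shape != (3, 3):
        raise ValueError("expected a 3x3 class table")
    lod = (_loglik_codominant(counts, r_hat) - _loglik_codominant(counts, 0.5)) / math.log(10.0)
    return max(lod, 0.0)


# ---------------------------------------------------------------------------
# map assembly and interval arithmetic
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Cumulative Kosambi map along a fixed (physical) marker order."""

    markers: list[str]
    cum_cm: list[float]
    trait_name: str | None = None
    trait_interval: tuple[str, str] | None = None
    trait_cm: float | None = None
    notes: list[str] = field(default_factory=list)


def assemble_map(
    marker_order: Sequence[str],
    adjacent_estimates: Sequence[LinkageEstimate],
    trait_estimates: dict[str, LinkageEstimate] | None = None,
    trait_name: str = "trait",
) -> GeneticMap:
    """Build a cumulative cM map from adjacent-pair estimates.

    ``adjacent_estimates[i]`` must link ``marker_order[i]`` to
    ``marker_order[i+1]``.  If per-marker trait estimates are supplied,
    the trait is placed in the interval whose two flanking markers have
    the smallest summed trait-marker Kosambi distances.
    """
    markers = list(marker_order)
    if len(markers) == 1:
        return GeneticMap(markers=markers, cum_cm=[0.0], trait_name=trait_name)
    if len(adjacent_estimates) != len(markers) - 1:
        raise ValueError(
            f"need {len(markers) - 1} adjacent estimates for {len(markers)} markers, "
            f"got {len(adjacent_estimates)}"
        )
    cum = [0.0]
    for est in adjacent_estimates:
        d = est.d_kosambi_cm
        if math.isinf(d):
            raise ValueError(f"adjacent pair {est.pair} is unlinked (r >= 0.5)")
        cum.append(cum[-1] + d)
    gmap = GeneticMap(markers=markers, cum_cm=cum, trait_name=trait_name)
    if trait_estimates:
        missing = [m for m in markers if m not in trait_estimates]
        if missing:
            raise ValueError(f"missing trait estimates for markers: {missing}")
        dists = [trait_estimates[m].d_kosambi_cm for m in markers]
        best = min(range(len(markers) - 1), key=lambda i: dists[i] + dists[i + 1])
        gmap.trait_interval = (markers[best], markers[best + 1])
        # place the trait inside the interval, proportional to flank distances
        left, right = dists[best], dists[best + 1]
        span = cum[best + 1] - cum[best]
        frac = 0.5 if left + right == 0 else min(left / (left + right), 1.0)
        gmap.trait_cm = cum[best] + frac * span
    return gmap


def interval_span_kb(start_bp: int, end_bp: int) -> int:
    """Physical span of a 1-based inclusive interval, rounded to integer kb."""
    if start_bp > end_bp:
        raise ValueError(f"start ({start_bp}) exceeds end ({end_bp})")
    return round((end_bp - start_bp) / 1000.0)
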
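"""Per-population variability measures, HWE tests, pairwise FST and
null-allele estimation for co-dominant diploid matrices.

He is plain gene diversity 1 - sum(p^2) (no small-sample correction), Ne the
effective allele number 1/sum(p^2), FIS = (He - Ho)/He. Pairwise FST defaults
to a Nei-style ratio-of-sums over loci with unweighted pooling of the two
populations; Weir & Cockerham's theta is available as an alternative. Null
alleles are estimated per population and locus with an EM algorithm over
allele frequencies augmented by a null allele, treating observed homozygotes
as mixtures of true homozygotes and visible/null heterozygotes and blanks as
null homozygotes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Hashable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import AlleleLabel, GenotypeMatrix

Pair = tuple[Hashable, Hashable]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleFreqTable:
    """Per (population, locus): allele -> frequency plus the count of typed
    individuals."""

    freqs: dict[tuple[str, str], dict[AlleleLabel, float]]
    n_typed: dict[tuple[str, str], int]


def allele_freqs(m: GenotypeMatrix) -> AlleleFreqTable:
    freqs: dict[tuple[str, str], dict[AlleleLabel, float]] = {}
    n_typed: dict[tuple[str, str], int] = {}
    for pop in m.populations:
        samples = m.samples_in(pop)
        for locus in m.loci:
            counts: dict[AlleleLabel, int] = {}
            n = 0
            for s in samples:
                pair = m.get(s, locus)
                if pair is None:
                    continue
                n += 1
                for a in pair:
                    counts[a] = counts.get(a, 0) + 1
            key = (pop, locus)
            n_typed[key] = n
            if n:
                total = 2 * n
                freqs[key] = {a: c / total for a, c in counts.items()}
            else:
                freqs[key] = {}
    return AlleleFreqTable(freqs, n_typed)


# ---------------------------------------------------------------------------
# variability summaries
# ---------------------------------------------------------------------------


@dataclass
class LocusStats:
    n: int
    na: int
    ne: float
    ho: float
    he: float
    fis: float | None  # None when He == 0


@dataclass
class VariabilitySummary:
    per_locus: dict[tuple[str, str], LocusStats]
    per_population: dict[str, dict[str, tuple[float, float]]]  # stat -> (mean, SE)
    hwe: dict[tuple[str, str], "HweResult"]
    hwe_deviation_count: dict[str, int]  # loci with p < alpha per population

    def mean(self, population: str, stat: str) -> float:
        return self.per_population[population][stat][0]


def _mean_se(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return (math.nan, math.nan)
    if arr.size == 1:
        return (float(arr[0]), 0.0)
    return (float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size)))


def variability(m: GenotypeMatrix, alpha: float = 0.05) -> VariabilitySummary:
    """Per-population N, Na, Ne, Ho, He (mean ± SE across loci), per-locus
    FIS, and chi-square HWE deviation counts at ``alpha``.

    A (population, locus) cell with no typed individual is excluded from that
    population's means. Raises if a population has no typed data at all.
    """
    table = allele_freqs(m)
    per_locus: dict[tuple[str, str], LocusStats] = {}
    hwe: dict[tuple[str, str], HweResult] = {}
    hwe_count: dict[str, int] = {}
    per_population: dict[str, dict[str, tuple[float, float]]] = {}
    for pop in m.populations:
        samples = m.samples_in(pop)
        cols: dict[str, list[float]] = {k: [] for k in ("N", "Na", "Ne", "Ho", "He")}
        n_dev = 0
        for locus in m.loci:
            key = (pop, locus)
            n = table.n_typed[key]
            if n == 0:
                continue
            p = np.array(list(table.freqs[key].values()))
            sum_p2 = float((p**2).sum())
            na = int((p > 0).sum())
            ne = 1.0 / sum_p2
            het = sum(
                1
                for s in samples
                if (pair := m.get(s, locus)) is not None and pair[0] != pair[1]
            )
            ho = het / n
            he = 1.0 - sum_p2
            fis = (he - ho) / he if he > 0 else None
            per_locus[key] = LocusStats(n, na, ne, ho, he, fis)
            res = hwe_test(genotype_counts(m, pop, locus)[0])
            hwe[key] = res
            if res.testable and res.p < alpha:
                n_dev += 1
            cols["N"].append(n)
            cols["Na"].append(na)
            cols["Ne"].append(ne)
            cols["Ho"].append(ho)
            cols["He"].append(he)
        if not cols["N"]:
            raise ValueError(f"population {pop!r} has no typed data")
        per_population[pop] = {k: _mean_se(v) for k, v in cols.items()}
        hwe_count[pop] = n_dev
    return VariabilitySummary(per_locus, per_population, hwe, hwe_count)


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------


@dataclass
class HweResult:
    chi2: float
    df: int
    p: float
    testable: bool = True


def genotype_counts(
    m: GenotypeMatrix, population: str, locus: str
) -> tuple[dict[Pair, int], int]:
    """Unordered genotype-class counts plus the number of blank (untyped)
    individuals for one population and locus."""
    counts: dict[Pair, int] = {}
    blanks = 0
    for s in m.samples_in(population):
        pair = m.get(s, locus)
        if pair is None:
            blanks += 1
        else:
            key = tuple(sorted(pair))
            counts[key] = counts.get(key, 0) + 1
    return counts, blanks


def hwe_test(counts: Mapping[Pair, int]) -> HweResult:
    """Chi-square goodness-of-fit over all k(k+1)/2 genotype classes against
    Hardy-Weinberg expectations, df = k(k-1)/2. Monomorphic data is not
    testable."""
    norm: dict[Pair, int] = {}
    for pair, c in counts.items():
        a, b = sorted(pair)
        norm[(a, b)] = norm.get((a, b), 0) + c
    n = sum(norm.values())
    allele_counts: dict[Hashable, int] = {}
    for (a, b), c in norm.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
    alleles = sorted(allele_counts)
    k = len(alleles)
    if k < 2 or n == 0:
        return HweResult(math.nan, 0, math.nan, testable=False)
    p = {a: allele_counts[a] / (2 * n) for a in alleles}
    chi2 = 0.0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            expected = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
            observed = norm.get((a, b), 0)
            if expected > 0:
                chi2 += (observed - expected) ** 2 / expected
    df = k * (k - 1) // 2
    return HweResult(chi2, df, float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# pairwise FST
# ---------------------------------------------------------------------------


@dataclass
class FstMatrix:
    populations: list[str]
    values: np.ndarray
    estimator: str

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.populations.index(a), self.populations.index(b)])


def _nei_fst(
    table: AlleleFreqTable, loci: Sequence[str], pop_a: str, pop_b: str
) -> float:
    sum_ht = 0.0
    sum_hs = 0.0
    informative = 0
    for locus in loci:
        fa = table.freqs[(pop_a, locus)]
        fb = table.freqs[(pop_b, locus)]
        if not fa or not fb:
            continue
        informative += 1
        alleles = set(fa) | set(fb)
        he_a = 1.0 - sum(v**2 for v in fa.values())
        he_b = 1.0 - sum(v**2 for v in fb.values())
        hs = (he_a + he_b) / 2.0
        ht = 1.0 - sum(
            ((fa.get(al, 0.0) + fb.get(al, 0.0)) / 2.0) ** 2 for al in alleles
        )
        sum_hs += hs
        sum_ht += ht
    if informative == 0 or sum_ht == 0.0:
        raise ValueError(f"no informative loci for pair ({pop_a}, {pop_b})")
    return max(0.0, (sum_ht - sum_hs) / sum_ht)


def _wc_theta(
    m: GenotypeMatrix, table: AlleleFreqTable, loci: Sequence[str], pops: Sequence[str]
) -> float:
    """Weir & Cockerham (1984) theta summed over alleles and loci."""
    r = len(pops)
    num = 0.0
    den = 0.0
    for locus in loci:
        ns = [table.n_typed[(p, locus)] for p in pops]
        if any(n < 2 for n in ns):
            continue
        alleles = sorted(
            {a for p in pops for a in table.freqs[(p, locus)]}
        )
        if len(alleles) < 2:
            continue
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n**2 for n in ns) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        # observed heterozygote frequency involving each allele
        hobs: dict[Any, list[float]] = {a: [0.0] * r for a in alleles}
        for i, pop in enumerate(pops):
            het_counts: dict[Any, int] = {a: 0 for a in alleles}
            for s in m.samples_in(pop):
                pair = m.get(s, locus)
                if pair is None or pair[0] == pair[1]:
                    continue
                het_counts[pair[0]] += 1
                het_counts[pair[1]] += 1
            for a in alleles:
                hobs[a][i] = het_counts[a] / ns[i]
        for a in alleles:
            ps = [table.freqs[(p, locus)].get(a, 0.0) for p in pops]
            pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hobs[a])) / (r * nbar)
            va = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
            )
            vb = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - s2 * (r - 1) / r
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            vc = hbar / 2.0
            num += va
            den += va + vb + vc
    if den == 0.0:
        raise ValueError(f"no informative loci for populations {list(pops)}")
    return num / den


def pairwise_fst(
    m: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    estimator: str = "nei_ratio_of_means",
) -> float:
    """Pairwise FST between two populations across all loci.

    ``nei_ratio_of_means`` (default): per locus Hs is the unweighted mean of
    the two populations' gene diversities and Ht the gene diversity of the
    mean allele-frequency vector; FST is the ratio of sums across loci,
    clamped at >= 0. ``weir_cockerham``: theta (1984), the moment estimator
    unbiased for Balding-Nichols F.
    """
    if pop_a == pop_b:
        return 0.0
    table = allele_freqs(m)
    if estimator in ("nei_ratio_of_means", "nei"):
        return _nei_fst(table, m.loci, pop_a, pop_b)
    if estimator in ("weir_cockerham", "wc"):
        return max(0.0, _wc_theta(m, table, m.loci, [pop_a, pop_b]))
    raise ValueError(f"unknown estimator {estimator!r}")


def fst_matrix(m: GenotypeMatrix, estimator: str = "nei_ratio_of_means") -> FstMatrix:
    pops = m.populations
    values = np.zeros((len(pops), len(pops)))
    for i, a in enumerate(pops):
        for j in range(i + 1, len(pops)):
            v = pairwise_fst(m, a, pops[j], estimator)
            values[i, j] = values[j, i] = v
    return FstMatrix(pops, values, estimator)


# ---------------------------------------------------------------------------
# null-allele EM (FreeNA-style, Dempster EM)
# ---------------------------------------------------------------------------


@dataclass
class NullAlleleEstimate:
    r_hat: float
    iterations: int
    converged: bool
    log_likelihood: float
    visible_freqs: dict[Hashable, float] = field(default_factory=dict)


def null_allele_em(
    counts: Mapping[Pair, int],
    n_blank: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    include_blanks: bool = True,
) -> NullAlleleEstimate:
    """EM estimate of the null-allele frequency r at one locus in one
    population.

    The model augments the visible alleles with a null allele under
    Hardy-Weinberg: visible heterozygotes are observed directly, an observed
    homozygote i/i is a mixture of true i/i and i/null, and blanks are
    null/null. With ``include_blanks`` False the likelihood conditions on a
    visible genotype (FreeNA offers both conventions) and blanks are ignored.
    The log-likelihood is non-decreasing across iterations.
    """
    norm: dict[Pair, int] = {}
    for pair, c in counts.items():
        a, b = sorted(pair)
        norm[(a, b)] = norm.get((a, b), 0) + c
    alleles = sorted({a for pair in norm for a in pair})
    if not alleles:
        raise ValueError("no observed genotypes")
    n_obs = sum(norm.values())
    k = len(alleles)
    idx = {a: i for i, a in enumerate(alleles)}

    het = np.zeros(k)  # per-allele count in visible heterozygotes
    hom = np.zeros(k)  # observed homozygote class counts
    for (a, b), c in norm.items():
        if a == b:
            hom[idx[a]] += c
        else:
            het[idx[a]] += c
            het[idx[b]] += c

    # init: frequencies from observed allele counts, a small null share
    p = (2 * hom + het).astype(float)
    p /= p.sum()
    r = 0.1
    p = p * (1 - r)

    def loglik(p: np.ndarray, r: float) -> float:
        ll = 0.0
        for (a, b), c in norm.items():
            if a == b:
                prob = p[idx[a]] ** 2 + 2 * p[idx[a]] * r
            else:
                prob = 2 * p[idx[a]] * p[idx[b]]
            ll += c * math.log(max(prob, 1e-300))
        if include_blanks:
            if n_blank:
                ll += n_blank * math.log(max(r**2, 1e-300))
        else:
            ll -= n_obs * math.log(max(1 - r**2, 1e-300))
        return ll

    prev_ll = -math.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        e_hom_true = np.zeros(k)
        e_hom_null = np.zeros(k)
        for i in range(k):
            if hom[i] == 0:
                continue
            denom = p[i] + 2 * r
            if denom <= 0:
                continue
            e_hom_true[i] = hom[i] * p[i] / denom
            e_hom_null[i] = hom[i] * 2 * r / denom
        if include_blanks:
            e_blank = float(n_blank)
        else:
            e_blank = n_obs * r**2 / max(1 - r**2, 1e-12)
        n_eff = n_obs + e_blank
        # M-step
        new_p = (2 * e_hom_true + het + e_hom_null) / (2 * n_eff)
        new_r = (e_hom_null.sum() + 2 * e_blank) / (2 * n_eff)
        delta = max(abs(new_r - r), float(np.max(np.abs(new_p - p))))
        p, r = new_p, new_r
        ll = loglik(p, r)
        if ll < prev_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        prev_ll = ll
        if delta < tol:
            converged = True
            break
    return NullAlleleEstimate(
        float(min(max(r, 0.0), 1.0)),
        it,
        converged,
        prev_ll,
        {a: float(p[idx[a]]) for a in alleles},
    )


def estimate_null_alleles(
    m: GenotypeMatrix, include_blanks: bool = True, **em_kwargs
) -> dict[tuple[str, str], NullAlleleEstimate]:
    out: dict[tuple[str, str], NullAlleleEstimate] = {}
    for pop in m.populations:
        for locus in m.loci:
            counts, blanks = genotype_counts(m, pop, locus)
            if not counts:
                continue
            out[(pop, locus)] = null_allele_em(
                counts, blanks, include_blanks=include_blanks, **em_kwargs
            )
    return out


def flag_null_markers(
    estimates: Mapping[tuple[str, str], NullAlleleEstimate | float],
    threshold: float = 0.2,
) -> dict[str, dict[str, Any]]:
    """Per-marker null-allele verdicts: a population-level flag when r-hat
    strictly exceeds ``threshold`` there, and a global flag only when every
    population with an estimate exceeds it."""
    by_locus: dict[str, dict[str, float]] = {}
    for (pop, locus), est in estimates.items():
        r = est.r_hat if isinstance(est, NullAlleleEstimate) else float(est)
        by_locus.setdefault(locus, {})[pop] = r
    out: dict[str, dict[str, Any]] = {}
    for locus, per_pop in by_locus.items():
        flags = {pop: r > threshold for pop, r in per_pop.items()}
        out[locus] = {
            "per_population": flags,
            "global": all(flags.values()) and bool(flags),
        }
    return out
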
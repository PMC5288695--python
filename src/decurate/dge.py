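"""Negative-binomial exact-test differential expression over a time course.

The workflow mirrors the classic count-based DE protocol for de novo
assemblies: libraries are equalised to a common size, a common dispersion
is estimated across contigs, and each pair of time points is compared
with a conditional NB exact test.  A contig is called differentially
expressed when any of the six time-point pairs reaches |log2FC| >= 2 at
Benjamini-Hochberg FDR <= 0.01 (both bounds inclusive).

Dispersion is the median over contigs of a method-of-moments estimate
pooled across replicate groups — a closed-form, testable stand-in for
likelihood-based common-dispersion estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import false_discovery_control

from .io import groups_by_timepoint


@dataclass
class DEResult:
    """Long-format DE table plus the per-contig overall call.

    ``table`` has one row per contig x time-point pair with columns
    ``contig_id, pair, log2fc, pvalue, fdr``; ``de_flags`` is a boolean
    Series over contigs.
    """

    table: pd.DataFrame
    de_flags: pd.Series
    dispersion: float
    lfc_min: float
    fdr_max: float

    def de_contigs(self) -> list[str]:
        return [c for c, f in self.de_flags.items() if f]


def _geometric_mean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def _library_sizes(
    counts: pd.DataFrame,
    sheet: pd.DataFrame | None = None,
    library_sizes: pd.Series | None = None,
) -> np.ndarray:
    """Resolve per-sample library sizes for normalisation.

    Explicit sizes win; otherwise a ``library_size`` column in the sample
    sheet (written by the synthetic generator, or by a quantifier that
    knows total mapped reads) is used; the fallback is the column sums,
    appropriate when the matrix covers the whole transcriptome.
    """
    if library_sizes is not None:
        lib = library_sizes.reindex(counts.columns).to_numpy(dtype=float)
    elif sheet is not None and "library_size" in sheet.columns:
        lib = (
            sheet.set_index("sample_id")["library_size"]
            .reindex(counts.columns)
            .to_numpy(dtype=float)
        )
    else:
        lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.isnan(lib).any() or (lib <= 0).any():
        raise ValueError("library sizes must be positive for every sample")
    return lib


def equalise_libraries(
    counts: pd.DataFrame, library_sizes: np.ndarray | None = None
) -> tuple[pd.DataFrame, float]:
    """Scale every sample to the geometric-mean library size, rounding to ints.

    The conditional exact test requires equal library sizes; rounding bias
    is negligible at the depths this pipeline works at.
    """
    lib = (
        np.asarray(library_sizes, dtype=float)
        if library_sizes is not None
        else counts.sum(axis=0).to_numpy(dtype=float)
    )
    if (lib <= 0).any():
        raise ValueError("every sample needs at least one count")
    common = _geometric_mean(lib)
    scaled = np.rint(counts.to_numpy(dtype=float) * (common / lib)).astype(np.int64)
    return pd.DataFrame(scaled, index=counts.index, columns=counts.columns), common


def estimate_common_dispersion(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    library_sizes: pd.Series | None = None,
) -> float:
    """Common NB dispersion phi by median-of-moments.

    Counts are first equalised to a common library size.  Per contig the
    moment identity var = mu + phi*mu^2 gives phi = (s^2 - m) / m^2; the
    numerators and denominators are pooled over the replicate groups and
    the estimate is the median over contigs of max(0, phi_contig).
    """
    groups = [g for g in groups_by_timepoint(sheet).values() if len(g) >= 2]
    if not groups:
        raise ValueError("dispersion estimation needs a group with >= 2 replicates")
    lib = _library_sizes(counts, sheet, library_sizes)
    scaled = counts.to_numpy(dtype=float) * (_geometric_mean(lib) / lib)
    cols = {c: j for j, c in enumerate(counts.columns)}
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    for g in groups:
        block = scaled[:, [cols[s] for s in g]]
        m = block.mean(axis=1)
        s2 = block.var(axis=1, ddof=1)
        num += s2 - m
        den += m * m
    ok = den > 0
    if not ok.any():
        raise ValueError("all contigs have zero counts")
    phi = np.maximum(0.0, num[ok] / den[ok])
    return float(np.median(phi))


def _log_nb_pmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """log PMF of NB with var = mean + phi*mean^2; phi=0 is Poisson."""
    k = np.asarray(k, dtype=float)
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if phi <= 0:
        return k * np.log(mean) - mean - gammaln(k + 1)
    r = 1.0 / phi
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1)
        + r * np.log(r / (r + mean))
        + k * np.log(mean / (r + mean))
    )


def _conditional_p(a: int, s: int, n_a: int, n_b: int, phi: float) -> float:
    """Exact conditional p for observing group sums (a, s-a).

    Under the null both groups share a per-replicate mean mu = s/(n_a+n_b);
    the sum of n i.i.d. NB(mu, phi) draws is NB(n*mu, phi/n).  Conditional
    on the total s, the p-value is the total probability of all splits no
    more likely than the observed one (two-sided by construction).
    """
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    mu = s / (n_a + n_b)
    logp = _log_nb_pmf(k, n_a * mu, phi / n_a) + _log_nb_pmf(k[::-1], n_b * mu, phi / n_b)
    logp -= logp.max()
    p = np.exp(logp)
    obs = p[a] * (1.0 + 1e-12)  # tolerate float ties in symmetric splits
    return float(p[p <= obs].sum() / p.sum())


def exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    phi: float,
    lib_a: np.ndarray | None = None,
    lib_b: np.ndarray | None = None,
) -> float:
    """NB exact test between two replicate groups of one contig.

    Counts are scaled to the geometric-mean library size, rounded, and
    summed within each group before the conditional test.  With phi=0 and
    equal single-replicate libraries this reduces to the binomial
    conditional test.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if lib_a is None and lib_b is None:
        a_scaled, b_scaled = counts_a, counts_b
    else:
        lib_a = np.asarray(lib_a, dtype=float)
        lib_b = np.asarray(lib_b, dtype=float)
        common = _geometric_mean(np.concatenate([lib_a, lib_b]))
        a_scaled = np.rint(counts_a * (common / lib_a))
        b_scaled = np.rint(counts_b * (common / lib_b))
    a = int(round(a_scaled.sum()))
    b = int(round(b_scaled.sum()))
    return _conditional_p(a, a + b, len(counts_a), len(counts_b), phi)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values), input order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return false_discovery_control(p, method="bh")


def call_de(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    dispersion: float | None = None,
    lfc_min: float = 2.0,
    fdr_max: float = 0.01,
    pseudo_cpm: float = 0.5,
    library_sizes: pd.Series | None = None,
) -> DEResult:
    """Run the full pairwise exact-test scan and flag DE contigs.

    All unordered time-point pairs are tested; BH adjustment is applied
    within each pair separately.  log2FC is later-over-earlier time point,
    computed from pseudo-counted CPM means.  The overall DE flag is the
    union over pairs of (FDR <= fdr_max) AND (|log2FC| >= lfc_min), both
    inclusive.

    Library sizes follow :func:`_library_sizes`: pass them explicitly when
    the matrix covers only a subset of the transcriptome (the synthetic
    generator records them in the sample sheet).
    """
    groups = groups_by_timepoint(sheet)
    if len(groups) < 2:
        raise ValueError("need at least two time points")
    for tp, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"time point {tp} has fewer than 2 replicates")
    missing = [s for g in groups.values() for s in g if s not in counts.columns]
    if missing:
        raise ValueError(f"samples missing from count matrix: {missing[:5]}")

    ordered = counts[[s for g in groups.values() for s in g]]
    lib = _library_sizes(ordered, sheet, library_sizes)
    lib_series = pd.Series(lib, index=ordered.columns)
    scaled, common = equalise_libraries(ordered, lib)
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, sheet, lib_series)

    cpm_mean = {
        tp: counts[g].div(lib_series[g], axis=1).mean(axis=1) * 1e6
        for tp, g in groups.items()
    }
    group_sums = {tp: scaled[g].sum(axis=1).to_numpy() for tp, g in groups.items()}
    n_reps = {tp: len(g) for tp, g in groups.items()}

    frames = []
    contigs = counts.index
    for t1, t2 in combinations(sorted(groups), 2):
        a_sum, b_sum = group_sums[t1], group_sums[t2]
        pvals = np.array(
            [
                _conditional_p(int(a), int(a) + int(b), n_reps[t1], n_reps[t2], dispersion)
                for a, b in zip(a_sum, b_sum)
            ]
        )
        lfc = np.log2((cpm_mean[t2] + pseudo_cpm) / (cpm_mean[t1] + pseudo_cpm))
        frames.append(
            pd.DataFrame(
                {
                    "contig_id": contigs,
                    "pair": f"{t1}-{t2}",
                    "log2fc": lfc.to_numpy(),
                    "pvalue": pvals,
                    "fdr": bh_adjust(pvals),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    hit = (table["fdr"] <= fdr_max) & (table["log2fc"].abs() >= lfc_min)
    de_flags = (
        table.loc[hit, "contig_id"].pipe(lambda s: pd.Series(True, index=s.unique()))
        .reindex(contigs, fill_value=False)
    )
    de_flags.name = "de"
    return DEResult(table, de_flags, float(dispersion), lfc_min, fdr_max)
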
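"""Time-point categorisation against physiological baseline, and
expression-profile subclustering.

Categorisation assigns each DE contig a direction (up / down / ns) at
every treatment time point.  When the contig is significant directly
against the 0-hps control, the direction comes from that comparison.
When it is significant only among treatment time points, a physiological
baseline is inferred from the control replicates and a weaker
replicate-consistency rule applies.  Contigs whose direction cannot be
assigned anywhere — the classic symptom being inconsistent replicate
signs with large between-replicate variance — are flagged
uncategorisable and dropped from downstream accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dge import DEResult
from .io import groups_by_timepoint

TREATMENT_TPS = (3, 20, 96)


@dataclass
class TimepointCategories:
    """Per-contig categories: a frame with columns cat3/cat20/cat96
    (up|down|ns), basis (direct | baseline_inferred | none) and an
    uncategorisable flag."""

    table: pd.DataFrame

    def categorisable(self) -> list[str]:
        t = self.table
        return list(t.index[~t["uncategorisable"]])


def categorise_timepoints(
    de_result: DEResult,
    log2_expr: pd.DataFrame,
    sheet: pd.DataFrame,
    contigs: list[str] | None = None,
    delta_min: float = 1.0,
    cv_max: float = 0.5,
) -> TimepointCategories:
    """Categorise DE contigs at 3, 20 and 96 hps against baseline.

    ``log2_expr`` holds log2(FPKM + 1) per replicate (NOT median-centred;
    the replicate CV rule needs a scale-stable positive measure).

    For each treatment time point t: the 0-vs-t comparison passing the DE
    thresholds categorises directly by the sign of its log2FC.  Otherwise,
    if the contig is DE only among treatment pairs, the control mean is
    the inferred baseline and t is categorised when the mean deviation is
    >= ``delta_min`` with all replicates deviating in the same direction.
    A contig with no categorisable time point is uncategorisable; in the
    canonical case its implicated time points show replicate CV above
    ``cv_max``.
    """
    if contigs is None:
        contigs = de_result.de_contigs()
    groups = groups_by_timepoint(sheet)
    table = de_result.table
    sig = table[
        (table["fdr"] <= de_result.fdr_max)
        & (table["log2fc"].abs() >= de_result.lfc_min)
    ]
    sig_by_contig: dict[str, pd.DataFrame] = {
        cid: grp for cid, grp in sig.groupby("contig_id")
    }

    control_cols = groups.get(0, [])
    rows = []
    for cid in contigs:
        if cid not in set(de_result.de_flags.index):
            raise KeyError(f"contig {cid} absent from DE table")
        cats = {tp: "ns" for tp in TREATMENT_TPS}
        basis = "none"
        contig_sig = sig_by_contig.get(cid)
        pairs = set(contig_sig["pair"]) if contig_sig is not None else set()

        # direct rule: significant against the 0-hps control
        for tp in TREATMENT_TPS:
            pair = f"0-{tp}"
            if pair in pairs:
                lfc = float(contig_sig.loc[contig_sig["pair"] == pair, "log2fc"].iloc[0])
                cats[tp] = "up" if lfc > 0 else "down"
                basis = "direct"

        implicated: set[int] = set()
        treatment_only = basis != "direct" and bool(pairs)
        if treatment_only:
            for pair in pairs:
                a, b = (int(x) for x in pair.split("-"))
                implicated.update(tp for tp in (a, b) if tp != 0)
            baseline = float(log2_expr.loc[cid, control_cols].mean())
            for tp in sorted(implicated):
                reps = log2_expr.loc[cid, groups[tp]].to_numpy(dtype=float)
                dev = reps - baseline
                if abs(dev.mean()) >= delta_min and (np.all(dev > 0) or np.all(dev < 0)):
                    cats[tp] = "up" if dev.mean() > 0 else "down"
                    basis = "baseline_inferred"

        uncategorisable = all(c == "ns" for c in cats.values())
        high_cv = False
        if uncategorisable and implicated:
            cvs = []
            for tp in sorted(implicated):
                reps = log2_expr.loc[cid, groups[tp]].to_numpy(dtype=float)
                m = reps.mean()
                cvs.append(np.inf if m == 0 else reps.std(ddof=1) / abs(m))
            high_cv = all(cv > cv_max for cv in cvs)
        if uncategorisable:
            cats = {tp: "ns" for tp in TREATMENT_TPS}
        rows.append(
            {
                "contig_id": cid,
                "cat3": cats[3],
                "cat20": cats[20],
                "cat96": cats[96],
                "basis": basis,
                "uncategorisable": uncategorisable,
                "high_replicate_cv": high_cv,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "contig_id", "cat3", "cat20", "cat96",
            "basis", "uncategorisable", "high_replicate_cv",
        ],
    ).set_index("contig_id")
    return TimepointCategories(frame)


# ---------------------------------------------------------------------------
# subclustering
# ---------------------------------------------------------------------------

@dataclass
class SubclusterSet:
    assignments: pd.Series  # contig -> subcluster id (1..k)
    mean_profiles: pd.DataFrame  # subcluster x samples
    linkage_matrix: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.max()) if len(self.assignments) else 0


def _correlation_distance(mat: np.ndarray) -> np.ndarray:
    """1 - Pearson between rows, safe for constant rows (which are treated
    as mutually identical and maximally distant from varying rows)."""
    sd = mat.std(axis=1)
    const = sd == 0
    centred = mat - mat.mean(axis=1, keepdims=True)
    norm = np.where(const, 1.0, np.linalg.norm(centred, axis=1))
    unit = centred / norm[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    if const.any():
        corr[const, :] = 0.0
        corr[:, const] = 0.0
        corr[np.ix_(const, const)] = 1.0
    np.fill_diagonal(corr, 1.0)
    return 1.0 - corr


def subcluster(
    log2mc: pd.DataFrame,
    cut_fraction: float = 0.5,
    linkage_method: str = "complete",
) -> SubclusterSet:
    """Hierarchical subclustering of contig expression profiles.

    Complete-linkage agglomeration on 1 - Pearson distances; flat
    subclusters come from cutting the dendrogram at ``cut_fraction`` of
    its maximum merge height.  Rows are processed in id-sorted order so
    the partition is invariant to input row order; subcluster ids are
    numbered by first appearance in that order.
    """
    if log2mc.shape[0] < 2 or log2mc.shape[1] < 2:
        raise ValueError("need at least 2 contigs and 2 samples")
    ordered = log2mc.sort_index()
    dist = _correlation_distance(ordered.to_numpy(dtype=float))
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    # small absolute slack so numerically-zero trees collapse to one cluster
    height = cut_fraction * z[:, 2].max() + 1e-9
    raw = fcluster(z, t=height, criterion="distance")
    # renumber in order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    assignments = pd.Series(labels, index=ordered.index, name="subcluster")
    means = ordered.groupby(assignments).mean()
    means.index.name = "subcluster"
    return SubclusterSet(assignments, means, z)


def sample_correlation(
    log2mc: pd.DataFrame, linkage_method: str = "complete"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pearson correlation between sample columns plus a sample dendrogram.

    Zero-variance columns yield missing correlations (reported as NaN).
    """
    if log2mc.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    corr = log2mc.corr(method="pearson")
    filled = corr.fillna(0.0).to_numpy()
    np.fill_diagonal(filled, 1.0)
    z = linkage(squareform(1.0 - filled, checks=False), method=linkage_method)
    return corr, z
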
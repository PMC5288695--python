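"""Time-point categorisation and expression-profile subclustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from decurate.dge import DEResult
from decurate.profiles import categorise_timepoints, sample_correlation, subcluster
from decurate.synth import SimDesign, simulate_counts
from decurate import quant
from conftest import archetype_manifest, random_lengths


def _sheet():
    rows = [
        {"sample_id": f"hps{tp}_r{r}", "timepoint_hps": tp, "replicate": r}
        for tp in (0, 3, 20, 96)
        for r in (1, 2, 3)
    ]
    return pd.DataFrame(rows)


def _de_result(rows, contigs):
    """DEResult with a hand-written significance table."""
    all_rows = []
    for cid in contigs:
        for pair in ("0-3", "0-20", "0-96", "3-20", "3-96", "20-96"):
            match = [r for r in rows if r[0] == cid and r[1] == pair]
            if match:
                _, _, lfc, fdr = match[0]
            else:
                lfc, fdr = 0.0, 1.0
            all_rows.append(
                {"contig_id": cid, "pair": pair, "log2fc": lfc, "pvalue": fdr, "fdr": fdr}
            )
    table = pd.DataFrame(all_rows)
    hit = (table["fdr"] <= 0.01) & (table["log2fc"].abs() >= 2)
    flags = pd.Series(False, index=pd.Index(contigs))
    flags[table.loc[hit, "contig_id"].unique()] = True
    return DEResult(table, flags, 0.2, 2.0, 0.01)


def _expr(values):
    """log2 expression frame; values keyed contig -> 12 per-sample numbers."""
    return pd.DataFrame.from_dict(values, orient="index", columns=_sheet()["sample_id"])


class TestCategorise:
    def test_direct_rule_single_timepoint(self):
        de = _de_result([("c1", "0-20", 3.0, 0.001)], ["c1"])
        expr = _expr({"c1": [5, 5, 5, 5, 5, 5, 8, 8, 8, 5, 5, 5]})
        cats = categorise_timepoints(de, expr, _sheet()).table
        assert tuple(cats.loc["c1", ["cat3", "cat20", "cat96"]]) == ("ns", "up", "ns")
        assert cats.loc["c1", "basis"] == "direct"
        assert not cats.loc["c1", "uncategorisable"]

    def test_baseline_inferred_rule(self):
        """Significant only for the 3-vs-20 pair; 3 hps replicates sit +2
        above the control-inferred baseline, 20 hps at baseline."""
        de = _de_result([("c1", "3-20", -2.5, 0.001)], ["c1"])
        expr = _expr({"c1": [5, 5, 5, 7, 7, 7, 5, 5, 5, 5, 5, 5]})
        cats = categorise_timepoints(de, expr, _sheet()).table
        assert tuple(cats.loc["c1", ["cat3", "cat20", "cat96"]]) == ("up", "ns", "ns")
        assert cats.loc["c1", "basis"] == "baseline_inferred"

    def test_inconsistent_replicates_uncategorisable(self):
        """Mixed replicate signs with high CV at every implicated time
        point: the contig cannot be assigned a direction."""
        de = _de_result([("c1", "3-20", 2.5, 0.001)], ["c1"])
        expr = _expr({"c1": [5, 5, 5, 9, 1, 6, 1, 9, 5, 5, 5, 5]})
        cats = categorise_timepoints(de, expr, _sheet()).table
        assert cats.loc["c1", "uncategorisable"]
        assert cats.loc["c1", "high_replicate_cv"]
        assert tuple(cats.loc["c1", ["cat3", "cat20", "cat96"]]) == ("ns", "ns", "ns")

    def test_replicate_order_invariance(self):
        de = _de_result([("c1", "0-3", 2.5, 0.001)], ["c1"])
        vals = [5, 5, 5, 9, 8, 9.5, 5, 5, 5, 5, 5, 5]
        expr = _expr({"c1": vals})
        sheet = _sheet()
        shuffled = sheet.sample(frac=1, random_state=3)
        a = categorise_timepoints(de, expr, sheet).table
        b = categorise_timepoints(de, expr, shuffled).table
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_contig_rejected(self):
        de = _de_result([], ["c1"])
        with pytest.raises(KeyError):
            categorise_timepoints(de, _expr({"c1": [0] * 12}), _sheet(), contigs=["zz"])


class TestSubcluster:
    def test_identical_rows_single_cluster(self, rng):
        base = rng.normal(size=8)
        m = pd.DataFrame([base] * 10, index=[f"c{i}" for i in range(10)])
        assert subcluster(m).n_clusters == 1

    def test_two_orthogonal_archetypes_exact(self, rng):
        design = SimDesign(dispersion=0.05, seed=21)
        arch = np.array([3] * 50 + [2] * 50)
        man = archetype_manifest(100, rng, arch)
        counts, sheet = simulate_counts(man, design, random_lengths(100, rng), rng)
        lib = sheet.set_index("sample_id")["library_size"]
        mc = quant.log2_median_center(quant.fpkm(counts, random_lengths(100, rng), lib))
        sc = subcluster(mc)
        assert sc.n_clusters == 2
        assert adjusted_rand_score(arch, sc.assignments.reindex(man["contig_id"])) == 1.0

    def test_row_order_invariance(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(40, 12)), index=[f"c{i:02d}" for i in range(40)]
        )
        a = subcluster(m).assignments
        b = subcluster(m.sample(frac=1, random_state=1)).assignments
        assert a.sort_index().equals(b.sort_index())

    def test_partition_covers_all(self, rng):
        m = pd.DataFrame(rng.normal(size=(25, 6)), index=[f"c{i}" for i in range(25)])
        sc = subcluster(m)
        assert sorted(sc.assignments.index) == sorted(m.index)
        assert set(sc.assignments) == set(range(1, sc.n_clusters + 1))

    def test_too_few_contigs_rejected(self):
        with pytest.raises(ValueError):
            subcluster(pd.DataFrame([[1.0, 2.0]], index=["c"]))


class TestSampleCorrelation:
    def test_duplicated_column_unit_correlation(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        m["d"] = m["a"]
        corr, _ = sample_correlation(m)
        assert corr.loc["a", "d"] == pytest.approx(1.0)

    def test_negated_column_anticorrelated(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        m["neg"] = -m["a"]
        corr, _ = sample_correlation(m)
        assert corr.loc["a", "neg"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_psd(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 6)))
        corr, _ = sample_correlation(m)
        c = corr.to_numpy()
        assert np.allclose(c, c.T) and np.allclose(np.diag(c), 1.0)
        assert np.linalg.eigvalsh(c).min() > -1e-10

    def test_coinciding_timepoints_most_similar(self, rng):
        """When 0 hps and 96 hps share their expression profile, their
        samples correlate better with each other than with 20 hps."""
        design = SimDesign(dispersion=0.1, seed=31)
        # responses active at 3-20 hps that resolve by 96 hps, half up and
        # half down: expression at 0 hps and 96 hps coincides
        shapes = {1: (0.0, 4.0, 4.0, 0.0), 2: (0.0, -4.0, -4.0, 0.0)}
        arch = np.array([1] * 30 + [2] * 30)
        man = archetype_manifest(60, rng, arch, shapes=shapes)
        counts, sheet = simulate_counts(man, design, random_lengths(60, rng), rng)
        lib = sheet.set_index("sample_id")["library_size"]
        mc = quant.log2_median_center(quant.fpkm(counts, random_lengths(60, rng), lib))
        corr, _ = sample_correlation(mc)
        cross = corr.loc["hps0_r1", "hps96_r1"]
        to_active = corr.loc["hps0_r1", "hps20_r1"]
        assert cross > to_active

    def test_zero_variance_column_missing(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        corr, _ = sample_correlation(m)
        assert np.isnan(corr.loc["a", "b"])
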
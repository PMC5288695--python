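"""The synthetic-data generator: planted truth, invariants, determinism."""

import numpy as np
import pandas as pd
import pytest

from decurate.orfs import find_orfs, max_stopfree_run
from decurate.synth import (
    SimDesign,
    SyntheticDataset,
    diverge_proteome,
    make_noncoding,
    simulate_counts,
    simulate_dataset,
    simulate_proteome,
)
from conftest import archetype_manifest


class TestProteomes:
    def test_deterministic_under_seed(self):
        a = simulate_proteome(5, (50, 50), seed=7)
        b = simulate_proteome(5, (50, 50), seed=7)
        assert a == b
        assert all(len(s) == 50 and s[0] == "M" for s in a.values())

    def test_length_bounds(self):
        prots = simulate_proteome(100, (50, 500), seed=1)
        assert all(50 <= len(s) <= 500 for s in prots.values())

    def test_different_seeds_differ(self):
        assert simulate_proteome(10, (60, 100), seed=1) != simulate_proteome(
            10, (60, 100), seed=2
        )

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            simulate_proteome(0)

    def test_divergence_zero_is_identity(self):
        prots = simulate_proteome(5, (80, 120), seed=3)
        assert diverge_proteome(prots, 0.0, seed=1) == prots

    def test_divergence_rate_recovered(self):
        """Observed identity after divergence matches 1 - rate within a
        binomial confidence band (substitutions always change residues)."""
        prots = simulate_proteome(10, (100, 100), seed=4)
        div = diverge_proteome(prots, 0.2, seed=5)
        same = sum(
            a == b for p, q in zip(prots.values(), div.values()) for a, b in zip(p, q)
        )
        total = sum(len(p) for p in prots.values())
        assert same / total == pytest.approx(0.8, abs=0.04)

    def test_divergence_rate_bounds(self):
        prots = simulate_proteome(2, (50, 50), seed=1)
        with pytest.raises(ValueError):
            diverge_proteome(prots, 1.0)
        high = diverge_proteome(prots, 0.99, seed=1)
        assert high != prots


class TestNoncoding:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_certified_orf_free(self, seed):
        rng = np.random.default_rng(seed)
        seq = make_noncoding(rng, 600, min_aa=33)
        assert max_stopfree_run(seq) < 33
        assert find_orfs(seq, min_aa=33) == []


class TestDataset:
    def test_manifest_covers_contigs_exactly_once(self, small_dataset):
        ds, _ = small_dataset
        assert sorted(ds.manifest["contig_id"]) == sorted(ds.contigs)
        assert ds.manifest["contig_id"].is_unique

    def test_planted_orf_spans_valid(self, small_dataset):
        ds, _ = small_dataset
        clean = ds.manifest[ds.manifest["anomaly"] == "none"]
        for row in clean.itertuples():
            if row.orf_start < 0:
                continue
            seq = ds.contigs[row.contig_id]
            assert 0 <= row.orf_start < row.orf_end <= len(seq)
            assert (row.orf_end - row.orf_start) % 3 == 0
            orf_nt = seq[row.orf_start : row.orf_end]
            assert orf_nt.startswith("ATG")
            assert orf_nt[-3:] in ("TAA", "TAG", "TGA")

    def test_no_orf_class_certified(self, small_dataset):
        ds, _ = small_dataset
        noorf = ds.manifest[ds.manifest["class_label"] == "no_orf"]
        for row in noorf.itertuples():
            assert find_orfs(ds.contigs[row.contig_id], min_aa=33) == []

    def test_redundant_copies_highly_similar(self, small_dataset):
        from decurate.curation import pairwise_identity

        ds, _ = small_dataset
        dups = ds.manifest[ds.manifest["anomaly"].str.startswith("redundant_of")]
        for row in dups.itertuples():
            parent = row.anomaly.split(":")[1]
            assert pairwise_identity(ds.contigs[row.contig_id], ds.contigs[parent]) >= 0.96

    def test_fragment_pairs_reassemble(self, small_dataset):
        from decurate.curation import merge_fragments

        ds, _ = small_dataset
        frags = ds.manifest[ds.manifest["anomaly"].str.startswith("fragment_pair")]
        seen = set()
        for row in frags.itertuples():
            partner = row.anomaly.split(":")[1]
            key = tuple(sorted([row.contig_id, partner]))
            if key in seen:
                continue
            seen.add(key)
            merged = merge_fragments(ds.contigs[row.contig_id], ds.contigs[partner])
            assert merged == row.parent_sequence

    def test_anomaly_rates_approximate_binomial(self):
        design = SimDesign(n_contigs=400, seed=77)
        ds, _ = simulate_dataset(design)
        dups = ds.manifest["anomaly"].str.startswith("redundant_of").sum()
        expect = design.anomaly_rates["redundant"] * design.n_contigs
        sd = np.sqrt(expect)
        assert abs(dups - expect) <= 4 * sd + 2

    def test_write_read_roundtrip(self, small_dataset, tmp_path):
        ds, _ = small_dataset
        ds.write(tmp_path)
        back = SyntheticDataset.read(tmp_path, ds.design)
        assert back.contigs == ds.contigs
        assert back.ref_proteome == ds.ref_proteome
        assert back.prior_assembly == ds.prior_assembly
        assert list(back.manifest["contig_id"]) == list(ds.manifest["contig_id"])

    def test_byte_identical_under_seed(self, tmp_path):
        out = []
        for rep in range(2):
            ds, counts = simulate_dataset(SimDesign(n_contigs=60, seed=9))
            d = tmp_path / f"rep{rep}"
            ds.write(d)
            from decurate.io import write_counts

            write_counts(counts, d / "counts.tsv")
            out.append({p.name: p.read_bytes() for p in sorted(d.iterdir())})
        assert out[0] == out[1]

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimDesign(class_fractions={"annotated": 0.5, "no_orf": 0.2})


class TestCounts:
    def test_poisson_limit(self, rng):
        design = SimDesign(dispersion=0.0, seed=10, library_size_range=(1e6, 1e6))
        man = archetype_manifest(1, rng)
        man["mean_fpkm_0"] = 100.0
        lengths = pd.Series([1000], index=man["contig_id"])
        draws = []
        for i in range(400):
            c, _ = simulate_counts(man, design, lengths, np.random.default_rng(i))
            draws.append(c.iloc[0, 0])
        draws = np.array(draws, dtype=float)
        assert np.var(draws) / draws.mean() == pytest.approx(1.0, abs=0.3)

    def test_nb_moments(self):
        """phi=0.5, mu=100: var should be mu + phi mu^2 = 5100 within 10%."""
        rng = np.random.default_rng(3)
        lam = rng.gamma(shape=1 / 0.5, scale=100 * 0.5, size=10000)
        draws = rng.poisson(lam)
        assert np.var(draws) == pytest.approx(5100, rel=0.1)

    def test_null_group_means_converge(self, rng):
        """A null contig's per-time-point means differ only by sampling
        noise: the spread shrinks with replicate count."""
        man = archetype_manifest(1, rng)
        lengths = pd.Series([1000], index=man["contig_id"])
        spreads = {}
        for reps in (3, 100):
            design = SimDesign(dispersion=0.2, replicates=reps, seed=5)
            counts, sheet = simulate_counts(man, design, lengths, np.random.default_rng(5))
            by_tp = counts.T.groupby(sheet.set_index("sample_id")["timepoint_hps"]).mean()
            m = by_tp.iloc[:, 0]
            spreads[reps] = m.max() - m.min()
        assert spreads[100] < spreads[3]

    def test_negative_means_rejected(self, rng):
        man = archetype_manifest(1, rng)
        man["mean_fpkm_3"] = -1.0
        with pytest.raises(ValueError):
            simulate_counts(man, SimDesign(seed=1), pd.Series([500], index=man["contig_id"]))
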
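import json

import numpy as np
import pytest

from finemapkit.annotation import read_bedgraph
from finemapkit.fourc import build_fragment_map
from finemapkit.ld import r2_from_haplotypes
from finemapkit.synthetic_data import (
    EMSA_CONTEXT,
    LocusDesign,
    add_genotype_uncertainty,
    expected_fragment_weights,
    simulate_4c_reads,
    simulate_case_control,
    simulate_expression,
    simulate_haplotypes,
    write_fixture_locus,
)


class TestSimulateHaplotypes:
    def test_perfect_ld_gives_identical_columns(self):
        h = simulate_haplotypes([0.4, 0.4], [1.0, 1.0], 5_000, seed=0)
        np.testing.assert_array_equal(h[:, 0], h[:, 1])

    def test_r2_and_frequency_convergence(self):
        h = simulate_haplotypes([0.35, 0.35], [1.0, 0.91], 100_000, seed=1)
        assert r2_from_haplotypes(h[:, 0], h[:, 1]).r2 == pytest.approx(0.91, abs=0.02)
        np.testing.assert_allclose(h.mean(axis=0), [0.35, 0.35], atol=0.02)

    def test_count_table_matches_closed_form(self):
        h = simulate_haplotypes([0.3, 0.45], [1.0, 0.5], 20_000, seed=2)
        a, b = h[:, 0], h[:, 1]
        n = len(a)
        f11 = np.sum((a == 1) & (b == 1)) / n
        pA, pB = a.mean(), b.mean()
        oracle = (f11 - pA * pB) ** 2 / (pA * (1 - pA) * pB * (1 - pB))
        assert r2_from_haplotypes(a, b).r2 == pytest.approx(oracle, abs=1e-12)

    def test_infeasible_r2_names_maximum(self):
        with pytest.raises(ValueError, match="maximum achievable r2"):
            simulate_haplotypes([0.35, 0.05], [1.0, 0.9], 100, seed=0)


class TestSimulateCaseControl:
    def test_null_effect_equalizes_frequencies(self):
        h = simulate_haplotypes([0.35], [1.0], 20_000, seed=3)
        table, y = simulate_case_control(h, 0, 1.0, 2_000, 2_000, seed=4)
        case_raf = table.dosages[y == 1, 0].mean() / 2
        ctrl_raf = table.dosages[y == 0, 0].mean() / 2
        assert case_raf == pytest.approx(ctrl_raf, abs=0.03)

    def test_rare_disease_case_frequency_closed_form(self):
        p, or_ = 0.35, 1.35
        h = simulate_haplotypes([p], [1.0], 20_000, seed=5)
        table, y = simulate_case_control(h, 0, or_, 4_000, 1_000, baseline_risk=0.001, seed=6)
        expected = p * or_ / (1 - p + p * or_)
        assert table.dosages[y == 1, 0].mean() / 2 == pytest.approx(expected, abs=0.02)

    def test_raf_difference_sign_tracks_log_or(self):
        h = simulate_haplotypes([0.3], [1.0], 20_000, seed=7)
        for or_ in (0.7, 1.35, 2.0):
            table, y = simulate_case_control(h, 0, or_, 1_500, 1_500, seed=8)
            diff = table.dosages[y == 1, 0].mean() - table.dosages[y == 0, 0].mean()
            assert np.sign(diff) == np.sign(np.log(or_))

    def test_seeded_determinism_and_quotas(self):
        h = simulate_haplotypes([0.4], [1.0], 5_000, seed=9)
        t1, y1 = simulate_case_control(h, 0, 1.3, 300, 500, seed=10)
        t2, y2 = simulate_case_control(h, 0, 1.3, 300, 500, seed=10)
        np.testing.assert_array_equal(t1.dosages, t2.dosages)
        np.testing.assert_array_equal(y1, y2)
        assert int(y1.sum()) == 300 and len(y1) == 800

    def test_unreachable_quota_reports_attained_counts(self):
        h = simulate_haplotypes([0.4], [1.0], 100, seed=11)
        with pytest.raises(RuntimeError, match="attained"):
            simulate_case_control(
                h, 0, 1.3, 5_000, 10, baseline_risk=0.001, seed=12, max_draws=20_000
            )


class TestGenotypeUncertainty:
    def test_triples_normalized_and_mode_is_truth(self):
        rng = np.random.default_rng(13)
        g = rng.integers(0, 3, size=(1_000, 4))
        probs = add_genotype_uncertainty(g, 0.9)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-12)
        assert probs.max(axis=-1).mean() == pytest.approx(0.9, abs=0.02)
        np.testing.assert_array_equal(probs.argmax(axis=-1), g)

    def test_certainty_one_reproduces_hard_calls(self):
        g = np.array([[0, 1, 2]])
        probs = add_genotype_uncertainty(g, 1.0)
        np.testing.assert_array_equal(probs[0], np.eye(3))

    def test_low_certainty_rejected(self):
        with pytest.raises(ValueError):
            add_genotype_uncertainty(np.array([[1]]), 1.0 / 3.0)


class TestSimulateExpression:
    def test_ols_recovers_generating_slope(self):
        rng = np.random.default_rng(14)
        dose = rng.binomial(2, 0.35, size=426).astype(float)
        expr = simulate_expression(dose, beta_per_allele=-0.5, noise_sd=1.0, seed=15)
        y = expr.expression_of("BMF")
        slope = np.polyfit(dose, y, 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(np.ones(10), noise_sd=0.0)

    def test_seeded_determinism(self):
        dose = np.tile([0.0, 1.0, 2.0], 20)
        a = simulate_expression(dose, seed=16)
        b = simulate_expression(dose, seed=16)
        np.testing.assert_array_equal(a.values, b.values)


@pytest.fixture(scope="module")
def fmap():
    seq = "".join(np.array(list("ACGT"))[np.random.default_rng(17).integers(0, 4, 60_000)])
    return build_fragment_map({"chrT": seq})


class TestSimulate4C:
    def test_pure_decay_weights_decrease_with_distance(self, fmap):
        vp = len(fmap.fragments) // 2
        w = expected_fragment_weights(fmap, vp, decay_exponent=1.0)
        mids = (fmap.fragments["start"] + fmap.fragments["end"]).to_numpy() / 2
        d = np.abs(mids - mids[vp])
        order = np.argsort(d)[1:]
        assert np.all(np.diff(w[order]) <= 1e-12)

    def test_masked_interval_gets_no_reads(self, fmap):
        masked = (20_000, 30_000)
        reads = simulate_4c_reads(
            fmap, len(fmap.fragments) // 4, 1.0, masked_interval=masked, n_reads=5_000, seed=18
        )
        inside = (reads["start"] >= masked[0]) & (reads["start"] < masked[1])
        assert not inside.any()

    def test_empty_fragment_map_rejected(self, fmap):
        import pandas as pd

        from finemapkit.fourc import FragmentMap

        empty = FragmentMap(
            pd.DataFrame(columns=["chrom", "start", "end", "blind"]), "GATC", "AAGCTT"
        )
        with pytest.raises(ValueError):
            simulate_4c_reads(empty, 0, n_reads=10, seed=0)


class TestFixtureLocus:
    def test_small_fixture_is_deterministic(self, tmp_path, small_design):
        m1 = write_fixture_locus(small_design, tmp_path / "a")
        m2 = write_fixture_locus(small_design, tmp_path / "b")
        assert {k: v["sha256"] for k, v in m1["files"].items()} == {
            k: v["sha256"] for k, v in m2["files"].items()
        }

    def test_existing_outdir_requires_overwrite(self, tmp_path, small_design):
        out = tmp_path / "c"
        out.mkdir()
        (out / "junk").write_text("x")
        with pytest.raises(FileExistsError):
            write_fixture_locus(small_design, out)

    def test_conservation_scores_at_causal_position(self, fixture_dir):
        design = LocusDesign()
        causal0 = design.causal_pos - 1
        phast = read_bedgraph(fixture_dir / "phastcons.bedgraph")
        hit = [iv for iv in phast if iv.start <= causal0 < iv.end]
        assert len(hit) == 1 and hit[0].value == 1.00
        assert hit[0].end - hit[0].start == 10  # the full motif footprint
        gerp = read_bedgraph(fixture_dir / "gerp.bedgraph")
        hit = [iv for iv in gerp if iv.start <= causal0 < iv.end]
        assert len(hit) == 1 and hit[0].value == 4.81

    def test_genome_context_around_causal_snp(self, fixture_dir):
        from pyfaidx import Fasta

        design = LocusDesign()
        fa = Fasta(str(fixture_dir / "genome.fa"))
        local = design.causal_pos - design.locus_start  # 0-based in record
        seq = str(fa[design.chrom][local - 11 : local + 12])
        assert seq == EMSA_CONTEXT
        assert seq[11] == "C"  # non-risk allele in the reference sequence

    def test_manifest_lists_all_files_with_checksums(self, fixture_dir):
        manifest = json.loads((fixture_dir / "manifest.json").read_text())
        for name, meta in manifest["files"].items():
            assert (fixture_dir / name).exists()
            assert len(meta["sha256"]) == 64
        assert "genotypes.tsv" in manifest["files"]
        assert "config.json" in manifest["files"]
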
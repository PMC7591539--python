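"""PWM scanning and ridge motif-activity inference."""

import numpy as np
import pandas as pd
import pytest

import stressmito as sm
from stressmito.motifs import (
    PWM,
    compare_activities,
    infer_activities,
    read_meme,
    scan_promoters,
    write_meme,
)


def consensus_pwm(seq, motif_id="m", sharp=0.97):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((4, len(seq)), (1 - sharp) / 3)
    for j, b in enumerate(seq):
        mat[idx[b], j] = sharp
    return PWM(motif_id, mat)


class TestPWM:
    def test_column_sums_validated(self):
        with pytest.raises(ValueError, match="sum"):
            PWM("bad", np.full((4, 6), 0.3))

    def test_minimum_width(self):
        with pytest.raises(ValueError, match="width"):
            PWM("short", np.full((4, 3), 0.25))

    def test_meme_round_trip(self, tmp_path, sharp_pwms):
        write_meme(sharp_pwms, tmp_path / "m.meme")
        back = read_meme(tmp_path / "m.meme")
        assert [p.motif_id for p in back] == [p.motif_id for p in sharp_pwms]
        for a, b in zip(back, sharp_pwms):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-4)


class TestScan:
    def toy_bed(self, names, length):
        return pd.DataFrame(
            {"chrom": [f"chr_{n}" for n in names], "start": 0, "end": length,
             "name": names, "score": 0, "strand": "+"}
        )

    def test_planted_consensus_counted_once_per_promoter(self):
        # non-palindromic consensus in a low-information (poly-C)
        # background so only the planted site reaches the threshold
        site = "AACGTGGT"
        pwm = consensus_pwm(site)
        seqs, names = {}, []
        for i in range(5):
            bg = list("C" * 60)
            bg[20:28] = site
            seqs[f"chr_p{i}"] = "".join(bg)
            names.append(f"p{i}")
        counts = scan_promoters(seqs, self.toy_bed(names, 60), [pwm], threshold=10.0)
        np.testing.assert_array_equal(counts["m"].to_numpy(), 1)

    def test_reverse_strand_occurrence_counted(self):
        # 20-bp toy: plant the reverse complement of the consensus
        site = "ACGTTGCA"
        rc = "TGCAACGT"
        seq = "CCCC" + rc + "CCCCCCCC"
        assert len(seq) == 20
        pwm = consensus_pwm(site)
        counts = scan_promoters(
            {"chr_x": seq}, self.toy_bed(["x"], 20), [pwm], threshold=10.0
        )
        assert counts.loc["x", "m"] == 1

    def test_window_overhang_clipped(self):
        pwm = consensus_pwm("AACGTGGT")
        seq = "AACGTGGT" + "C" * 12
        bed = pd.DataFrame(
            {"chrom": ["chr_x"], "start": [-5], "end": [40], "name": ["x"],
             "score": [0], "strand": ["+"]}
        )
        counts = scan_promoters({"chr_x": seq}, bed, [pwm], threshold=10.0)
        assert counts.loc["x", "m"] == 1

    def test_missing_contig_listed_in_error(self):
        pwm = consensus_pwm("ACGTACGT")
        with pytest.raises(ValueError, match="chr_missing"):
            scan_promoters({"chr_x": "A" * 30}, self.toy_bed(["missing"], 30), [pwm])

    def test_scan_agrees_with_planted_truth(self):
        # near-deterministic, non-palindromic PWMs: planted sites are
        # essentially the consensus, so scan counts match the truth
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        pwms = []
        for i, cons in enumerate(["AACGTGGT", "TTGACCAG", "CACGTAAC"]):
            mat = np.full((4, 8), 0.001)
            for j, b in enumerate(cons):
                mat[idx[b], j] = 0.997
            pwms.append(PWM(f"m{i+1}", mat / mat.sum(axis=0)))
        seqs, bed, truth = sm.simulate_promoters(40, pwms, occurrence_rate=1.0, seed=2)
        counts = scan_promoters(seqs, bed, pwms, threshold=12.0)
        agree = (counts.to_numpy() == truth.to_numpy()).mean()
        assert agree > 0.9


class TestRidge:
    def test_identity_design_zero_penalty_returns_expression(self, rng):
        E = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"g{i}" for i in range(6)])
        N = pd.DataFrame(np.eye(6), index=E.index, columns=[f"m{i}" for i in range(6)])
        act = infer_activities(E, N, penalty=0.0)
        Ec = E.to_numpy() - E.to_numpy().mean(axis=1, keepdims=True)
        Nc = np.eye(6) - 1 / 6
        expect = np.linalg.lstsq(Nc, Ec, rcond=None)[0]
        np.testing.assert_allclose(act.activities.to_numpy(), expect, atol=1e-8)

    def test_scalar_ridge_closed_form(self):
        # N = (1, 0), E = (2, 0), lam = 1: A = N'E / (N'N + lam) = 2/2 = 1
        E = pd.DataFrame({"s1": [2.0, 0.0]}, index=["g1", "g2"])
        N = pd.DataFrame({"m": [1.0, 0.0]}, index=["g1", "g2"])
        act = infer_activities(E, N, penalty=1.0, center=False)
        assert act.activities.loc["m", "s1"] == pytest.approx(1.0)

    def test_identity_design_uncentered_identity(self, rng):
        E = pd.DataFrame(rng.normal(size=(5, 3)), index=[f"g{i}" for i in range(5)])
        N = pd.DataFrame(np.eye(5), index=E.index, columns=[f"m{i}" for i in range(5)])
        act = infer_activities(E, N, penalty=0.0, center=False)
        np.testing.assert_allclose(act.activities.to_numpy(), E.to_numpy(), atol=1e-10)

    def test_huge_penalty_shrinks_to_zero(self, rng):
        E = pd.DataFrame(rng.normal(size=(20, 3)))
        N = pd.DataFrame(rng.poisson(1.0, size=(20, 4)), index=E.index)
        act = infer_activities(E, N, penalty=1e9)
        assert np.abs(act.activities.to_numpy()).max() < 1e-6

    def test_normal_equations_residual_small(self, rng):
        E = pd.DataFrame(rng.normal(size=(50, 6)))
        N = pd.DataFrame(rng.poisson(1.0, size=(50, 5)), index=E.index)
        act = infer_activities(E, N, penalty=3.0)
        assert act.residual_norm < 1e-8

    def test_activity_scales_with_expression(self, rng):
        E = pd.DataFrame(rng.normal(size=(30, 4)))
        N = pd.DataFrame(rng.poisson(1.0, size=(30, 3)), index=E.index)
        a1 = infer_activities(E, N, penalty=1.0).activities
        a2 = infer_activities(E * 5.0, N, penalty=1.0).activities
        np.testing.assert_allclose(a2.to_numpy(), 5.0 * a1.to_numpy(), atol=1e-8)

    def test_zero_site_motif_flagged(self, rng):
        E = pd.DataFrame(rng.normal(size=(10, 3)))
        N = pd.DataFrame({"m1": rng.poisson(1.0, 10), "dead": 0}, index=E.index)
        act = infer_activities(E, N, penalty=1.0)
        assert act.zero_motifs == ["dead"]
        np.testing.assert_allclose(act.activities.loc["dead"], 0.0)

    def test_negative_penalty_rejected(self, rng):
        E = pd.DataFrame(rng.normal(size=(5, 2)))
        N = pd.DataFrame(rng.poisson(1.0, size=(5, 2)), index=E.index)
        with pytest.raises(ValueError):
            infer_activities(E, N, penalty=-1.0)


class TestCompare:
    def test_planted_activity_shift_ranks_first(self, sharp_pwms):
        hits = 0
        for seed in range(10):
            seqs, bed, truth = sm.simulate_promoters(150, sharp_pwms, seed=seed)
            E, groups = sm.simulate_motif_expression(truth, {"m1": 1.0}, seed=seed + 100)
            act = infer_activities(E, truth)
            out = compare_activities(act, groups)
            hits += out.iloc[0]["motif"] == "m1"
        assert hits >= 9

    def test_null_activities_calibrated(self, rng):
        A = pd.DataFrame(rng.normal(size=(40, 20)), columns=[f"s{i}" for i in range(20)])
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=A.columns)
        out = compare_activities(A, groups)
        assert (out.p_value < 0.05).mean() < 0.2

    def test_constant_activities_flagged(self):
        A = pd.DataFrame(np.ones((2, 8)), index=["m1", "m2"], columns=[f"s{i}" for i in range(8)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=A.columns)
        out = compare_activities(A, groups).set_index("motif")
        assert out.flagged.all()
        assert out.p_value.isna().all()

    def test_small_group_rejected(self, rng):
        A = pd.DataFrame(rng.normal(size=(3, 4)), columns=[f"s{i}" for i in range(4)])
        groups = pd.Series(["A", "B", "B", "B"], index=A.columns)
        with pytest.raises(ValueError):
            compare_activities(A, groups)
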
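"""Loop matching, recovery, APA, orientation classes, interval overlaps —
each checked against a quadratic brute-force oracle on randomized inputs."""

import numpy as np
import pandas as pd
import pytest

from contactdiff.contact_io import ContactMatrix
from contactdiff.evaluation import (
    APAConfig,
    LoopSet,
    anchor_peak_overlap,
    apa,
    classify_ctcf_orientation,
    classify_loops_ctcf,
    extract_pixel_values,
    label_ep_loops,
    match_loops,
    read_bedpe,
    recovery_fraction,
    top_loops,
    write_bedpe,
)

from conftest import random_matrix

RES = 5000


def random_loops(rng, n, n_bins=200, chrom="chrT", with_fdr=False):
    b1 = rng.integers(0, n_bins - 1, size=n)
    b2 = b1 + rng.integers(1, 40, size=n)
    b2 = np.minimum(b2, n_bins - 1)
    fdr = rng.random(n) if with_fdr else None
    return LoopSet(chrom=np.array([chrom] * n), bin1=b1, bin2=b2,
                   resolution=RES, fdr=fdr)


def brute_match(ref, qry, s):
    flags = []
    for c, i, j in zip(ref.chrom, ref.bin1, ref.bin2):
        hit = any(
            cq == c and abs(iq - i) <= s and abs(jq - j) <= s
            for cq, iq, jq in zip(qry.chrom, qry.bin1, qry.bin2)
        )
        flags.append(hit)
    return np.array(flags)


def brute_overlap(start, end, peaks):
    return any(ps < end and pe > start
               for ps, pe in zip(peaks["start"], peaks["end"]))


class TestMatchAndRecovery:
    def test_identical_sets_match_at_zero(self, rng):
        loops = random_loops(rng, 20)
        assert match_loops(loops, loops, 0).all()
        assert recovery_fraction(loops, loops, 0) == 1.0

    def test_extending_size_boundary(self):
        ref = LoopSet(chrom=np.array(["c"]), bin1=[10], bin2=[30],
                      resolution=RES)
        qry = LoopSet(chrom=np.array(["c"]), bin1=[13], bin2=[27],
                      resolution=RES)
        assert match_loops(ref, qry, 3).all()
        assert not match_loops(ref, qry, 2).any()

    def test_disjoint_sets_recover_nothing(self, rng):
        ref = random_loops(rng, 15, n_bins=100)
        qry = LoopSet(chrom=np.array(["c2"] * 5), bin1=[1] * 5,
                      bin2=[50] * 5, resolution=RES)
        assert recovery_fraction(ref, qry, 3) == 0.0

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_brute_force_oracle(self, rng, trial):
        ref = random_loops(rng, 200)
        qry = random_loops(rng, 200)
        for s in (0, 1, 2, 3):
            np.testing.assert_array_equal(match_loops(ref, qry, s),
                                          brute_match(ref, qry, s))

    def test_monotone_in_s_and_duplication_invariant(self, rng):
        ref = random_loops(rng, 100)
        qry = random_loops(rng, 100)
        fracs = [recovery_fraction(ref, qry, s) for s in range(4)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
        dup = LoopSet(chrom=np.concatenate([qry.chrom, qry.chrom]),
                      bin1=np.concatenate([qry.bin1, qry.bin1]),
                      bin2=np.concatenate([qry.bin2, qry.bin2]),
                      resolution=RES)
        assert recovery_fraction(ref, dup, 2) == \
            recovery_fraction(ref, qry, 2)

    def test_resolution_mismatch_rejected(self, rng):
        ref = random_loops(rng, 5)
        qry = LoopSet(chrom=ref.chrom, bin1=ref.bin1, bin2=ref.bin2,
                      resolution=1000)
        with pytest.raises(ValueError):
            match_loops(ref, qry, 1)


class TestTopLoops:
    def test_full_selection_is_identity(self, rng):
        loops = random_loops(rng, 30, with_fdr=True)
        sel = top_loops(loops, 30)
        assert sorted(zip(sel.bin1, sel.bin2)) == \
            sorted(zip(loops.bin1, loops.bin2))

    def test_selects_smallest_fdrs(self, rng):
        loops = random_loops(rng, 50, with_fdr=True)
        sel = top_loops(loops, 10)
        cut = np.sort(loops.fdr)[9]
        assert np.all(sel.fdr <= cut + 1e-15)

    def test_tie_break_deterministic(self, rng):
        loops = random_loops(rng, 40)
        loops.fdr = np.repeat([0.1, 0.2], 20)  # heavy ties at the cut
        a = top_loops(loops, 25)
        b = top_loops(loops, 25)
        np.testing.assert_array_equal(a.bin1, b.bin1)
        np.testing.assert_array_equal(a.bin2, b.bin2)
        # brute-force: lexicographic (fdr, chrom, bin1, bin2) order
        rows = sorted(zip(loops.fdr, loops.chrom, loops.bin1, loops.bin2))
        want = rows[:25]
        got = sorted(zip(a.fdr, a.chrom, a.bin1, a.bin2))
        assert got == sorted(want)

    def test_missing_fdr_rejected(self, rng):
        with pytest.raises(ValueError):
            top_loops(random_loops(rng, 5), 2)


class TestAPA:
    def test_uniform_matrix_unit_scores(self):
        n = 60
        iu, ju = np.triu_indices(n)
        m = ContactMatrix(chrom="chrT", resolution=RES, n_bins=n,
                          bin1=iu, bin2=ju, value=np.ones(len(iu)))
        loops = LoopSet(chrom=np.array(["chrT"] * 2), bin1=[10, 20],
                        bin2=[30, 45], resolution=RES)
        res = apa(m, loops, APAConfig(window=11, corner=3))
        for score in res.corner_scores.values():
            assert score == pytest.approx(1.0)

    def test_corner_score_direct_arithmetic(self):
        # averaged block center 10, one corner mean 2 -> that score is 5
        n = 31
        dense = np.full((n, n), 2.0)
        c = 15
        dense[c, c] = 10.0
        dense = np.triu(dense) + np.triu(dense, 1).T
        m = ContactMatrix.from_dense(dense, "chrT", RES)
        loops = LoopSet(chrom=np.array(["chrT"]), bin1=[c], bin2=[c],
                        resolution=RES)
        res = apa(m, loops, APAConfig(window=11, corner=3))
        assert res.corner_scores["upper_left"] == pytest.approx(5.0)

    def test_mean_submatrix_matches_slice_oracle(self, rng):
        m = random_matrix(rng, n_bins=80, density=0.8)
        loops = LoopSet(chrom=np.array(["chrT"] * 12),
                        bin1=rng.integers(10, 40, 12),
                        bin2=rng.integers(45, 70, 12), resolution=RES)
        cfg = APAConfig(window=11, corner=3)
        res = apa(m, loops, cfg)
        dense = m.to_dense(np.nan)
        blocks = [dense[i - 5:i + 6, j - 5:j + 6]
                  for i, j in zip(loops.bin1, loops.bin2)]
        want = np.nanmean(np.stack(blocks), axis=0)
        np.testing.assert_allclose(res.mean_submatrix, want, atol=1e-12)
        assert res.n_loops_used == 12

    def test_edge_loops_skipped_and_counted(self, rng):
        m = random_matrix(rng, n_bins=40, density=0.9)
        loops = LoopSet(chrom=np.array(["chrT"] * 3), bin1=[2, 20, 35],
                        bin2=[10, 30, 38], resolution=RES)
        res = apa(m, loops, APAConfig(window=11, corner=3))
        assert res.n_loops_used == 1 and res.n_loops_skipped == 2

    def test_raw_mode_filters_distance_band(self, rng):
        m = random_matrix(rng, n_bins=600, density=0.3)
        # distances: 10 bins (50 kb, below band), 100 bins (in), 450 (above)
        loops = LoopSet(chrom=np.array(["chrT"] * 3), bin1=[50, 100, 100],
                        bin2=[60, 200, 550], resolution=RES)
        res = apa(m, loops, APAConfig(window=11, corner=3, mode="raw"))
        assert res.n_loops_used == 1

    def test_corner_scores_scale_invariant(self, rng):
        m = random_matrix(rng, n_bins=80, density=0.9)
        scaled = ContactMatrix(chrom=m.chrom, resolution=m.resolution,
                               n_bins=m.n_bins, bin1=m.bin1, bin2=m.bin2,
                               value=m.value * 7.5, missing=m.missing)
        loops = LoopSet(chrom=np.array(["chrT"] * 5),
                        bin1=rng.integers(10, 30, 5),
                        bin2=rng.integers(40, 70, 5), resolution=RES)
        cfg = APAConfig(window=11, corner=3, mode="raw")
        a = apa(m, loops, cfg)
        b = apa(scaled, loops, cfg)
        for k in a.corner_scores:
            assert a.corner_scores[k] == pytest.approx(b.corner_scores[k])

    def test_window_geometry_validated(self):
        with pytest.raises(ValueError):
            APAConfig(window=10, corner=3)
        with pytest.raises(ValueError):
            APAConfig(window=11, corner=6)
        assert APAConfig.default_for(1000).window == 51
        assert APAConfig.default_for(1000).corner == 15


class TestCTCFOrientation:
    def test_paper_classes(self):
        assert classify_ctcf_orientation("+", "-") == "convergent"
        assert classify_ctcf_orientation("-", "+") == "divergent"
        assert classify_ctcf_orientation("+", "+") == "forward"
        assert classify_ctcf_orientation("-", "-") == "reverse"
        assert classify_ctcf_orientation(None, "-") == "unclassified"

    def test_toy_loop_set_counts(self):
        # 8 loops covering every class, counted by hand
        strands = [("+", "-")] * 3 + [("-", "+")] * 2 + [("+", "+")] \
            + [("-", "-")] + [(None, "+")]
        classes = [classify_ctcf_orientation(a, b) for a, b in strands]
        counts = {c: classes.count(c) for c in set(classes)}
        assert counts == {"convergent": 3, "divergent": 2, "forward": 1,
                          "reverse": 1, "unclassified": 1}

    def test_table_driven_classification_and_ambiguity(self):
        loops = LoopSet(chrom=np.array(["c", "c"]), bin1=[10, 40],
                        bin2=[20, 50], resolution=RES)
        motifs = pd.DataFrame({
            "chrom": ["c"] * 4,
            "start": [10 * RES, 20 * RES, 40 * RES, 40 * RES],
            "end": [10 * RES + 100, 20 * RES + 100,
                    40 * RES + 100, 40 * RES + 200],
            "strand": ["+", "-", "+", "-"],
        })
        got = classify_loops_ctcf(loops, motifs)
        assert got[0] == "convergent"
        assert got[1] == "unclassified"  # both strands on one anchor


class TestIntervalOverlaps:
    def test_abutting_peak_not_counted(self):
        loops = LoopSet(chrom=np.array(["c"]), bin1=[10], bin2=[20],
                        resolution=RES)
        ext = 5000
        # peak starts exactly at the extended end: zero-length intersection
        end_of_anchor1 = (10 + 1) * RES + ext
        peaks = pd.DataFrame({"chrom": ["c"], "start": [end_of_anchor1],
                              "end": [end_of_anchor1 + 500]})
        # anchor2 is far away from this peak too
        assert anchor_peak_overlap(loops, peaks, extension=ext) == 0.0

    def test_all_anchors_contain_peaks(self, rng):
        loops = random_loops(rng, 10)
        rows = []
        for b in np.concatenate([loops.bin1, loops.bin2]):
            rows.append(("chrT", b * RES + 100, b * RES + 200))
        peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        assert anchor_peak_overlap(loops, peaks, extension=5000) == 1.0

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_quadratic_oracle(self, rng, trial):
        loops = random_loops(rng, 60)
        peaks = pd.DataFrame({
            "chrom": ["chrT"] * 300,
            "start": rng.integers(0, 200 * RES, 300),
        })
        peaks["end"] = peaks["start"] + rng.integers(100, 3000, 300)
        ext = 5000
        got = anchor_peak_overlap(loops, peaks, extension=ext)
        anchors = loops.anchors(extension=ext)
        want = np.mean([
            brute_overlap(s, e, peaks)
            for s, e in zip(anchors["start"], anchors["end"])
        ])
        assert got == pytest.approx(want)

    def test_duplicate_anchors_deduplicated(self):
        # two loops sharing an anchor: 3 unique loci, not 4
        loops = LoopSet(chrom=np.array(["c", "c"]), bin1=[10, 10],
                        bin2=[30, 50], resolution=RES)
        assert len(loops.anchors()) == 3


class TestEPLabels:
    def test_definition_cases(self):
        loops = LoopSet(chrom=np.array(["c"] * 3), bin1=[10, 40, 70],
                        bin2=[20, 50, 80], resolution=RES)
        enh = pd.DataFrame({"chrom": ["c"] * 3,
                            "start": [10 * RES, 40 * RES, 50 * RES],
                            "end": [10 * RES + 50, 40 * RES + 50,
                                    50 * RES + 50]})
        pro = pd.DataFrame({"chrom": ["c"],
                            "start": [20 * RES], "end": [20 * RES + 50]})
        flags = label_ep_loops(loops, pro, enh, extension=0)
        assert flags[0]          # E one side, P the other
        assert not flags[1]      # both anchors only enhancers
        assert not flags[2]      # no annotation at all

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_quadratic_oracle(self, rng, trial):
        loops = random_loops(rng, 80)
        def table(n):
            start = rng.integers(0, 200 * RES, n)
            return pd.DataFrame({"chrom": ["chrT"] * n, "start": start,
                                 "end": start + rng.integers(200, 20000, n)})
        enh, pro = table(150), table(150)
        ext = 5000
        got = label_ep_loops(loops, pro, enh, extension=ext)
        want = []
        for i, j in zip(loops.bin1, loops.bin2):
            s1, e1 = i * RES - ext, (i + 1) * RES + ext
            s2, e2 = j * RES - ext, (j + 1) * RES + ext
            a1e, a1p = brute_overlap(s1, e1, enh), brute_overlap(s1, e1, pro)
            a2e, a2p = brute_overlap(s2, e2, enh), brute_overlap(s2, e2, pro)
            want.append((a1e and a2p) or (a1p and a2e))
        np.testing.assert_array_equal(got, np.array(want))


class TestExtractPixelValues:
    def test_stored_absent_and_missing_pixels(self):
        m = ContactMatrix(chrom="c", resolution=RES, n_bins=10,
                          bin1=[1], bin2=[5], value=[0.02],
                          missing=np.array([False] * 9 + [True]))
        loops = LoopSet(chrom=np.array(["c"] * 3), bin1=[1, 2, 3],
                        bin2=[5, 6, 9], resolution=RES)
        vals = extract_pixel_values(loops, m)
        assert vals[0] == pytest.approx(0.02)
        assert vals[1] == 0.0
        assert np.isnan(vals[2])

    def test_matches_dense_lookup_oracle(self, rng):
        m = random_matrix(rng, n_bins=50, n_missing=4, density=0.6)
        loops = random_loops(rng, 100, n_bins=50)
        vals = extract_pixel_values(loops, m)
        dense = m.to_dense(np.nan)
        want = dense[loops.bin1, loops.bin2]
        np.testing.assert_array_equal(np.isnan(vals), np.isnan(want))
        ok = ~np.isnan(want)
        np.testing.assert_allclose(vals[ok], want[ok])

    def test_out_of_range_rejected(self, rng):
        m = random_matrix(rng, n_bins=10)
        loops = LoopSet(chrom=np.array(["c"]), bin1=[5], bin2=[12],
                        resolution=RES)
        with pytest.raises(ValueError):
            extract_pixel_values(loops, m)


class TestBedpeIO:
    def test_round_trip(self, tmp_path, rng):
        loops = random_loops(rng, 25, with_fdr=True)
        path = str(tmp_path / "loops.bedpe")
        write_bedpe(loops, path)
        back = read_bedpe(path, RES)
        np.testing.assert_array_equal(back.bin1, loops.bin1)
        np.testing.assert_array_equal(back.bin2, loops.bin2)
        np.testing.assert_allclose(back.fdr, loops.fdr)
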
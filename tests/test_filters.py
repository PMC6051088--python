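"""Filter cascade: per-step fates, boundary values, E-value statistics,
Knm ID assignment."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from knmir.discover import HairpinCandidate, ReadLocus
from knmir.filters import (FilterReport, FilterThresholds, apply_filter_cascade,
                           assign_ids, gc_outlier_filter, homology_evalue,
                           karlin_altschul_params)

from .conftest import random_rna


def make_candidate(chrom="chr1", start=1000, n_reads=50, randfold_p=0.01,
                   mature=None, gc=0.5, signature=0.9, seed=0):
    rng = np.random.default_rng(seed)
    if mature is None:
        # A/C alphabet: GC content is the C fraction, and such matures
        # cannot align to a G/U-only database (no match is possible),
        # which lets cascade fixtures pin homology fates exactly
        n_gc = round(22 * gc)
        bases = ["C"] * n_gc + ["A"] * (22 - n_gc)
        rng.shuffle(bases)
        mature = "".join(bases)
    end = start + 70
    locus = ReadLocus(chrom, start, end, "+", np.ones(end - start, dtype=int),
                      [(mature, start, n_reads)], n_reads)
    gc_frac = (mature.count("G") + mature.count("C")) / len(mature)
    return HairpinCandidate(
        locus=locus, precursor_start=start, precursor_seq=mature + "AAAA" + mature,
        structure="." * (2 * len(mature) + 4), pairing_score=40,
        mature_seq=mature, mature_start=start, star_seq="",
        signature_score=signature, gc_fraction=gc_frac, randfold_p=randfold_p)


EMPTY_BED = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])


class TestCascade:
    def test_empty_input(self):
        retained, report = apply_filter_cascade([], EMPTY_BED, {})
        assert retained == []
        assert all(i == 0 and o == 0 for _, i, o in report.per_step)

    def test_read_support_boundary(self):
        nine = make_candidate(start=1000, n_reads=9, seed=1)
        ten = make_candidate(start=2000, n_reads=10, seed=2)
        retained, report = apply_filter_cascade([nine, ten], EMPTY_BED, {})
        assert nine not in retained and ten in retained
        assert report.per_step[0] == ("read_support", 2, 1)

    def test_structure_p_boundary_is_strict(self):
        at = make_candidate(start=1000, randfold_p=0.05, seed=3)
        under = make_candidate(start=2000, randfold_p=0.049, seed=4)
        retained, _ = apply_filter_cascade([at, under], EMPTY_BED, {})
        assert at not in retained and under in retained

    def test_planted_fates_per_step(self):
        """50 candidates built to pass plus 10 built to fail at each
        step: the retained set is exactly the planted-pass set and the
        report counts telescope."""
        rng = np.random.default_rng(42)
        passing = [make_candidate(start=10_000 + 200 * i, seed=100 + i)
                   for i in range(50)]
        fail_reads = [make_candidate(start=100_000 + 200 * i, n_reads=5, seed=200 + i)
                      for i in range(10)]
        fail_rrna = [make_candidate(start=120_000 + 200 * i, seed=300 + i)
                     for i in range(10)]
        rrna_bed = pd.DataFrame([{"chrom": "chr1", "start": c.locus.start,
                                  "end": c.locus.end, "name": "rRNA",
                                  "score": ".", "strand": "+"} for c in fail_rrna])
        fail_p = [make_candidate(start=140_000 + 200 * i, randfold_p=0.5, seed=400 + i)
                  for i in range(10)]
        fail_dup = [make_candidate(start=160_000 + 200 * i,
                                   mature=passing[i].mature_seq,
                                   signature=0.1, seed=500 + i)
                    for i in range(10)]
        known = {f"mir-{i}": "".join(rng.choice(list("GU"), size=22))
                 for i in range(10)}
        fail_known = [make_candidate(start=180_000 + 200 * i,
                                     mature=known[f"mir-{i}"], seed=600 + i)
                      for i in range(10)]
        # extreme-GC matures, each distinct by construction (a single
        # odd base at position i) so none collide at the duplicates step
        fail_gc = [make_candidate(
            start=200_000 + 200 * i,
            mature=("C" * i + "A" + "C" * (21 - i)) if i % 2
            else ("A" * i + "C" + "A" * (21 - i)),
            seed=700 + i) for i in range(10)]
        all_cands = (passing + fail_reads + fail_rrna + fail_p + fail_dup
                     + fail_known + fail_gc)
        retained, report = apply_filter_cascade(all_cands, rrna_bed, known)
        assert set(map(id, retained)) == set(map(id, passing))
        # counts telescope
        for (s1, i1, o1), (s2, i2, o2) in zip(report.per_step, report.per_step[1:]):
            assert o1 == i2
        assert report.per_step[0][1] == 110 and report.per_step[-1][2] == 50
        expected_outs = [100, 90, 80, 70, 60, 50]
        assert [o for _, _, o in report.per_step] == expected_outs

    def test_step_order_is_fixed(self):
        """A candidate failing both read support and the structure test is
        reported at read_support (the earlier step), pinning the order."""
        both = make_candidate(n_reads=5, randfold_p=0.9, seed=9)
        _, report = apply_filter_cascade([both], EMPTY_BED, {})
        (cid, step, _), = report.rejections
        assert step == "read_support"

    def test_missing_annotation_is_configuration_error(self):
        with pytest.raises(ValueError, match="annotation"):
            apply_filter_cascade([make_candidate()], None, {})

    def test_duplicates_keep_highest_signature(self):
        hi = make_candidate(start=1000, signature=0.95, seed=10)
        lo = make_candidate(start=5000, mature=hi.mature_seq, signature=0.7, seed=11)
        retained, _ = apply_filter_cascade([lo, hi], EMPTY_BED, {})
        assert retained == [hi]


class TestHomology:
    def test_empty_database_is_infinite(self):
        assert homology_evalue("ACGUACGUACGUACGUACGUAC", {}) == float("inf")

    def test_identical_22mer_is_annotated(self):
        rng = np.random.default_rng(3)
        q = random_rna(rng, 22)
        # even with 1e5 nt of database, a perfect 22-nt match is E << 0.1
        db = {"hit": q}
        db.update({f"bg{i}": random_rna(rng, 1000) for i in range(100)})
        assert homology_evalue(q, db) < 0.1

    def test_lambda_root_against_bisection(self):
        lam, _ = karlin_altschul_params(1, -2)

        def f(L):
            return 0.25 * math.exp(L) + 0.75 * math.exp(-2 * L) - 1

        lo, hi = 1e-6, 10.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        assert lam == pytest.approx((lo + hi) / 2, abs=1e-8)
        assert lam == pytest.approx(1.3327, abs=1e-4)

    def test_evalue_decreases_in_score(self):
        lam, K = karlin_altschul_params(1, -2)
        e = [K * 22 * 1e5 * math.exp(-lam * s) for s in range(10, 23)]
        assert all(a > b for a, b in zip(e, e[1:]))

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty query"):
            homology_evalue("", {"a": "ACGU"})


class TestGcOutlier:
    def test_identical_gc_nothing_removed(self):
        cands = [make_candidate(start=1000 * i, gc=0.5, seed=i) for i in range(5)]
        assert gc_outlier_filter(cands) == cands

    def test_single_outlier_removed(self):
        cands = [make_candidate(start=1000 * i, gc=0.5, seed=i) for i in range(20)]
        outlier = make_candidate(start=50_000, gc=0.0, seed=99)
        kept = gc_outlier_filter(cands + [outlier])
        assert outlier not in kept and len(kept) == 20

    def test_permutation_invariant(self):
        cands = [make_candidate(start=1000 * i, gc=g, seed=i)
                 for i, g in enumerate([0.3, 0.5, 0.5, 0.6, 0.95])]
        kept1 = {id(c) for c in gc_outlier_filter(cands)}
        kept2 = {id(c) for c in gc_outlier_filter(cands[::-1])}
        assert kept1 == kept2

    def test_single_candidate_passes_with_warning(self):
        c = make_candidate()
        with pytest.warns(UserWarning):
            assert gc_outlier_filter([c]) == [c]


class TestAssignIds:
    def test_single_candidate_chr22(self):
        c = make_candidate(chrom="chr22")
        assert assign_ids([c])[0].knm_id == "Knm22_1"

    def test_serials_follow_position_order(self):
        a = make_candidate(chrom="chr1", start=100, seed=1)
        b = make_candidate(chrom="chr1", start=50, seed=2)
        assign_ids([a, b])
        assert a.knm_id == "Knm1_2" and b.knm_id == "Knm1_1"

    def test_rerun_is_stable(self):
        cands = [make_candidate(start=1000 * i, seed=i) for i in range(5)]
        ids1 = [c.knm_id for c in assign_ids(cands)]
        ids2 = [c.knm_id for c in assign_ids(cands)]
        assert ids1 == ids2 and len(set(ids1)) == 5

    def test_duplicate_position_rejected(self):
        a = make_candidate(start=100, seed=1)
        b = make_candidate(start=100, seed=2)
        with pytest.raises(ValueError, match="duplicate"):
            assign_ids([a, b])


def test_thresholds_must_be_positive():
    with pytest.raises(ValueError, match="strictly positive"):
        FilterThresholds(structure_p_max=0.0)


def test_report_rejects_non_telescoping_counts():
    r = FilterReport()
    r.record("a", 10, 8)
    with pytest.raises(ValueError, match="telescope"):
        r.record("b", 9, 9)
    with pytest.raises(ValueError, match="increase"):
        r.record("b", 8, 9)
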
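"""Jaccard concordance grid, cut-off selection, and artifact filtering."""

import datetime
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from oncoyield.concordance import (
    ConcordanceGrid,
    CutoffGrid,
    concordance_grid,
    filter_by_cutoff,
    flag_indel_artifacts,
    jaccard_index,
    select_cutoff_pair,
)
from oncoyield.model import SampleRecord, VariantCall, VariantKey
from oncoyield.simulate import (
    SimulationConfig,
    artifact_flood_config,
    generate_cohort,
)

UNIVERSE = [VariantKey("chr1", 100 + i, "A", "T") for i in range(6)]


def _call(key, vaf, sample_id="s", indel=False, repeat=False):
    if indel:
        key = VariantKey(key.chrom, key.pos, key.ref + "A", key.ref)
    return VariantCall(key=key, gene="G", vaf=vaf, depth=1000, sample_id=sample_id,
                       repeat_context=repeat)


class TestJaccard:
    def test_identical_nonempty(self):
        s = set(UNIVERSE[:3])
        assert jaccard_index(s, set(s)) == 1.0

    def test_disjoint(self):
        assert jaccard_index(set(UNIVERSE[:2]), set(UNIVERSE[3:5])) == 0.0

    def test_half_overlap(self):
        a, b = set(UNIVERSE[:3]), set(UNIVERSE[1:4])
        assert jaccard_index(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        assert jaccard_index(set(), set()) == 1.0

    def test_exhaustive_subset_oracle(self):
        """Equality with explicit intersection/union counting over every
        pair of subsets of a 6-element universe."""
        subsets = [
            frozenset(c)
            for r in range(7)
            for c in itertools.combinations(UNIVERSE, r)
        ]
        for a in subsets:
            for b in subsets:
                both = sum(1 for x in UNIVERSE if x in a and x in b)
                either = sum(1 for x in UNIVERSE if x in a or x in b)
                expected = both / either if either else 1.0
                assert jaccard_index(set(a), set(b)) == expected
                assert jaccard_index(set(b), set(a)) == expected  # symmetry


class TestFilterByCutoff:
    def test_class_specific_cfdna_thresholds(self):
        snv = _call(UNIVERSE[0], 0.002)
        indel = _call(UNIVERSE[1], 0.003, indel=True)
        got = filter_by_cutoff([snv, indel], "cfDNA", 0.001, 0.005)
        assert got == {snv.key}

    def test_tissue_below_cutoff_empty(self):
        calls = [_call(k, 0.04) for k in UNIVERSE[:3]]
        assert filter_by_cutoff(calls, "tumor_tissue", 0.05) == set()

    def test_boundary_inclusive(self):
        call = _call(UNIVERSE[0], 0.05)
        assert filter_by_cutoff([call], "tumor_tissue", 0.05) == {call.key}

    def test_tissue_single_threshold_enforced(self):
        with pytest.raises(ValueError):
            filter_by_cutoff([], "tumor_tissue", 0.05, 0.01)

    @settings(derandomize=True, max_examples=50)
    @given(vafs=st.lists(st.floats(0.0, 1.0), min_size=0, max_size=20),
           hi=st.sampled_from([0.10, 0.05, 0.01, 0.005]),
           lo=st.sampled_from([0.05, 0.01, 0.005, 0.001]))
    def test_monotone_refinement(self, vafs, hi, lo):
        """Lowering the cut-off never removes variants."""
        if lo > hi:
            lo, hi = hi, lo
        calls = [_call(VariantKey("chr1", 10 + i, "A", "T"), v)
                 for i, v in enumerate(vafs)]
        assert filter_by_cutoff(calls, "cfDNA", hi) <= filter_by_cutoff(calls, "cfDNA", lo)


class TestConcordanceGrid:
    def test_identical_sets_all_ones(self):
        t = [_call(k, 0.5, "t") for k in UNIVERSE[:5]]
        c = [_call(k, 0.5, "c") for k in UNIVERSE[:5]]
        g = concordance_grid(t, c)
        assert set(g.ji.values()) == {1.0}
        assert len(g.ji) == 10  # full 2x5 grid

    def test_sub_threshold_artifacts_do_not_move_higher_cutoffs(self):
        t = [_call(k, 0.5, "t") for k in UNIVERSE[:3]]
        c = [_call(k, 0.5, "c") for k in UNIVERSE[:3]]
        c += [_call(UNIVERSE[4], 0.0005, "c")]  # below every cut-off ladder rung
        g = concordance_grid(t, c)
        assert set(g.ji.values()) == {1.0}

    def test_lower_cfdna_cutoff_recovers_diluted_somatic(self):
        """At tumor fraction 0.3 the cfDNA somatic VAFs sit below 10% but
        above 0.5%, so relaxing the cfDNA cut-off raises concordance."""
        cohort, _ = generate_cohort(SimulationConfig(
            n_patients=1, n_germline_het=0, n_somatic_clonal=15,
            tumor_fraction=0.3, snv_artifact_rate=0, indel_artifact_rate=0,
            depth_mean={"tumor_tissue": 2000.0, "cfDNA": 2000.0,
                        "germline_blood": 300.0},
            seed=5))
        p = cohort.patients[0]
        g = concordance_grid(p.tissue.calls, p.cfdna.calls)
        assert g.ji[(0.05, 0.005)] >= g.ji[(0.05, 0.10)]

    def test_empty_sets_flagged(self):
        g = concordance_grid([], [])
        assert g.empty_flagged == set(g.ji)


class TestSelectCutoffPair:
    def _uniform_grids(self, value=0.9, n=4):
        pairs = CutoffGrid().pairs
        return [ConcordanceGrid(f"P{i}", {p: value for p in pairs}) for i in range(n)]

    def test_identical_grids_select_lowest_pair(self):
        sel = select_cutoff_pair(self._uniform_grids())
        assert sel.chosen == (0.05, 0.001)
        assert all(c.p_adjusted == 1.0 for c in sel.comparisons)

    def test_requires_two_patients(self):
        with pytest.raises(ValueError):
            select_cutoff_pair(self._uniform_grids(n=1))

    def test_summary_reports_median_and_sd(self):
        sel = select_cutoff_pair(self._uniform_grids(value=0.91))
        med, sd = sel.summary[sel.chosen]
        assert med == pytest.approx(0.91)
        assert sd == pytest.approx(0.0)

    def test_artifact_flood_recovers_planted_pair(self):
        cohort, _ = generate_cohort(artifact_flood_config(seed=3))
        grids = [concordance_grid(p.tissue.calls, p.cfdna.calls, patient_id=p.patient_id)
                 for p in cohort]
        sel = select_cutoff_pair(grids)
        assert sel.chosen == (0.05, 0.005)


def test_concordance_tracks_tumor_fraction():
    """Concordance is patient-dependent: patients with low cfDNA tumor
    fraction have systematically lower concordance."""
    cohort, truth = generate_cohort(SimulationConfig(
        n_patients=12, n_germline_het=5, n_somatic_clonal=12,
        tumor_fraction_range=(0.02, 0.6), snv_artifact_rate=0,
        indel_artifact_rate=0, seed=21))
    tfs, jis = [], []
    for p in cohort:
        g = concordance_grid(p.tissue.calls, p.cfdna.calls)
        tfs.append(truth.tumor_fraction[p.patient_id])
        jis.append(g.ji[(0.05, 0.05)])
    rho, _ = spearmanr(tfs, jis)
    assert rho > 0


class TestIndelArtifactFilter:
    def _sample(self, sid, calls):
        return SampleRecord(sample_id=sid, patient_id=sid, material="cfDNA",
                            collection_date=datetime.date(2022, 1, 1), calls=calls)

    def test_recurrent_repeat_indel_flagged(self):
        key = VariantKey("chr3", 500, "AA", "A")
        samples = [
            self._sample(f"s{i}", [_call(key, 0.002, f"s{i}", repeat=True)])
            for i in range(3)
        ]
        # _call with indel=False keeps the key as given (already an indel)
        assert flag_indel_artifacts(samples) == {key}

    def test_high_vaf_indel_not_flagged(self):
        key = VariantKey("chr3", 500, "AA", "A")
        samples = [self._sample(f"s{i}", [_call(key, 0.02, f"s{i}", repeat=True)])
                   for i in range(3)]
        assert flag_indel_artifacts(samples) == set()

    def test_single_sample_indel_not_flagged(self):
        key = VariantKey("chr3", 500, "AA", "A")
        samples = [self._sample("s0", [_call(key, 0.002, "s0", repeat=True)])]
        assert flag_indel_artifacts(samples) == set()

    def test_non_repeat_context_not_flagged(self):
        key = VariantKey("chr3", 500, "AA", "A")
        samples = [self._sample(f"s{i}", [_call(key, 0.002, f"s{i}")])
                   for i in range(3)]
        assert flag_indel_artifacts(samples) == set()
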
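"""Cytosine context classification, clone calling and tissue comparison."""

import numpy as np
import pytest

from mitescan.bisulfite_methylation import (
    CONTEXTS,
    call_clone,
    classify_context,
    compare_tissues,
    position_profile,
    summarize_replicate,
)
from mitescan.synthetic_data import SimulationConfig, gen_bisulfite_clones


def _fragment(rng, length=400):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestClassifyContext:
    @pytest.mark.parametrize(
        "ref,pos,expected",
        [
            ("ACGA", 2, "CG"),
            ("ACAGA", 2, "CHG"),
            ("ACAAT", 2, "CHH"),
            ("ACCGA", 2, "CHG"),   # H may itself be C
            ("ACCCA", 2, "CHH"),
            ("ACG", 2, "edge"),    # fewer than two downstream bases
            ("AC", 2, "edge"),
            ("ACNGA", 2, "edge"),  # ambiguous downstream base
        ],
    )
    def test_contexts(self, ref, pos, expected):
        assert classify_context(ref, pos) == expected

    def test_non_cytosine_rejected(self):
        with pytest.raises(ValueError, match="not C"):
            classify_context("ACGT", 1)

    def test_partition_conserved(self, rng):
        # every non-edge C gets exactly one of CG/CHG/CHH
        for _ in range(20):
            ref = _fragment(rng, 200)
            n_c = sum(1 for i, b in enumerate(ref[:-2]) if b == "C")
            contexts = [
                classify_context(ref, i + 1) for i, b in enumerate(ref) if b == "C"
            ]
            non_edge = [c for c in contexts if c != "edge"]
            assert all(c in CONTEXTS for c in non_edge)
            assert len(non_edge) == n_c  # ACGT-only fragment: edge = last 2 bases only


class TestCallClone:
    def test_identical_clone_fully_methylated(self, rng):
        ref = _fragment(rng)
        result = call_clone(ref, ref)
        assert result.calls and all(c.methylated for c in result.calls)
        assert result.n_anomalies == 0

    def test_fully_converted_clone_unmethylated(self, rng):
        ref = _fragment(rng)
        converted = ref.replace("C", "T")
        result = call_clone(converted, ref)
        assert result.calls and not any(c.methylated for c in result.calls)

    def test_hand_walked_two_site_fragment(self):
        # ref ACGACAAT: C2 in CG context, C5 in CHH; clone reads C2 as T
        result = call_clone("ATGACAAT", "ACGACAAT")
        by_pos = {c.position: c for c in result.calls}
        assert by_pos[2].context == "CG" and not by_pos[2].methylated
        assert by_pos[5].context == "CHH" and by_pos[5].methylated

    def test_anomalous_base_counted_not_called(self):
        result = call_clone("AGGACAAT", "ACGACAAT")  # G at a reference C
        assert result.n_anomalies == 1
        assert {c.position for c in result.calls} == {5}

    def test_misclone_rejected_on_backbone_identity(self, rng):
        ref = _fragment(rng)
        garbage = _fragment(np.random.default_rng(999), len(ref))
        with pytest.raises(ValueError, match="mis-cloned"):
            call_clone(garbage, ref)

    def test_indel_clone_skips_gapped_cytosines(self, rng):
        ref = _fragment(rng, 120)
        c_positions = [i for i, b in enumerate(ref) if b == "C"]
        drop = c_positions[len(c_positions) // 2]
        clone = ref[:drop] + ref[drop + 1:]  # one C deleted
        result = call_clone(clone, ref)
        full = call_clone(ref, ref)
        assert 0 < len(result.calls) < len(full.calls) + 1


class TestSummaries:
    def test_fully_methylated_clones_give_100_percent(self, rng):
        ref = _fragment(rng)
        results = [call_clone(ref, ref, f"c{i}") for i in range(15)]
        for s in summarize_replicate(results):
            if s.n_sites:
                assert s.mc_percent == 100.0

    def test_fully_converted_clones_give_0_percent(self, rng):
        ref = _fragment(rng)
        conv = ref.replace("C", "T")
        results = [call_clone(conv, ref, f"c{i}") for i in range(15)]
        for s in summarize_replicate(results):
            if s.n_sites:
                assert s.mc_percent == 0.0

    def test_context_counts_sum_to_all(self, rng, config):
        ref = _fragment(rng, 300)
        reps, _ = gen_bisulfite_clones(config, ref, "leaf")
        results = [call_clone(s, ref, cid) for cid, s in reps["r1"].items()]
        summaries = summarize_replicate(results)
        by_ctx = {s.context: s for s in summaries}
        assert sum(by_ctx[c].n_sites for c in CONTEXTS) == by_ctx["all"].n_sites
        assert sum(by_ctx[c].n_methylated for c in CONTEXTS) == by_ctx["all"].n_methylated

    def test_invariant_to_clone_order(self, rng, config):
        ref = _fragment(rng, 300)
        reps, _ = gen_bisulfite_clones(config, ref, "leaf")
        results = [call_clone(s, ref, cid) for cid, s in reps["r1"].items()]
        fwd = summarize_replicate(results)
        rev = summarize_replicate(results[::-1])
        assert [(s.context, s.n_sites, s.n_methylated) for s in fwd] == [
            (s.context, s.n_sites, s.n_methylated) for s in rev
        ]

    def test_position_profile_reports_per_site_fractions(self, rng):
        ref = "ACGACAAT" * 5
        clones = [ref, ref.replace("C", "T")]
        results = [call_clone(s, ref, f"c{i}") for i, s in enumerate(clones)]
        profile = position_profile(results)
        assert all(frac == 0.5 for _, frac in profile.values())


class TestSimulatorRoundTrip:
    def test_estimates_converge_with_clone_count(self, rng):
        ref = _fragment(rng, 400)
        errs = {}
        for n_clones in (15, 500):
            config = SimulationConfig(seed=21, clones_per_replicate=n_clones, replicates=1)
            reps, probs = gen_bisulfite_clones(config, ref, "leaf")
            results = [call_clone(s, ref, cid) for cid, s in reps["r1"].items()]
            summaries = {s.context: s for s in summarize_replicate(results)}
            errs[n_clones] = max(
                abs(summaries[c].mc_percent - 100 * probs[c]) for c in CONTEXTS
            )
        assert errs[500] < errs[15]
        assert errs[500] < 2.0

    def test_chh_estimate_within_3_binomial_sd(self, rng):
        ref = _fragment(rng, 400)
        config = SimulationConfig(seed=22)
        reps, probs = gen_bisulfite_clones(config, ref, "leaf")
        n_meth = n_sites = 0
        for clones in reps.values():
            results = [call_clone(s, ref, cid) for cid, s in clones.items()]
            s = next(x for x in summarize_replicate(results) if x.context == "CHH")
            n_meth, n_sites = n_meth + s.n_methylated, n_sites + s.n_sites
        p = probs["CHH"]
        sd = np.sqrt(p * (1 - p) / n_sites)
        assert abs(n_meth / n_sites - p) <= 3 * sd


class TestCompareTissues:
    def _summaries(self, ref, tissue, config):
        reps, _ = gen_bisulfite_clones(config, ref, tissue)
        out = []
        for rid, clones in reps.items():
            results = [call_clone(s, ref, cid) for cid, s in clones.items()]
            out.append(summarize_replicate(results, replicate_id=rid))
        return out

    def test_identical_sets_compare_at_p_one(self, rng, config):
        ref = _fragment(rng, 300)
        a = self._summaries(ref, "leaf", config)
        comps = compare_tissues(a, a)
        assert all(c.p_value == 1.0 and c.difference == 0.0 for c in comps)

    def test_zero_variance_shift_flagged_degenerate(self, rng):
        from mitescan.bisulfite_methylation import MethylationSummary

        a = [[MethylationSummary("f", f"r{i}", c, 100, 50) for c in (*CONTEXTS, "all")]
             for i in range(3)]
        b = [[MethylationSummary("f", f"r{i}", c, 100, 80) for c in (*CONTEXTS, "all")]
             for i in range(3)]
        comps = compare_tissues(a, b)
        assert all(c.degenerate and c.p_value == 0.0 for c in comps)

    def test_single_replicate_rejected(self, rng, config):
        ref = _fragment(rng, 300)
        a = self._summaries(ref, "leaf", config)
        with pytest.raises(ValueError, match="replicates"):
            compare_tissues(a[:1], a)

    def test_leaf_pollen_chh_contrast_significant(self, rng):
        ref = _fragment(rng, 500)
        config = SimulationConfig(seed=23)
        comps = compare_tissues(
            self._summaries(ref, "leaf", config),
            self._summaries(ref, "pollen", config),
        )
        chh = next(c for c in comps if c.context == "CHH")
        assert chh.p_value < 0.01 and chh.mean_b < chh.mean_a
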
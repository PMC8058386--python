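"""Partial influence: definition identity, sign law, profiles and what-ifs."""

import random

import pandas as pd
import pytest

from tmmpsf.influence import (
    mean_sample_pi,
    neutralize_and_score,
    partial_influence,
    pi_profile,
)
from tmmpsf.preprocess import FoldChangeMatrix
from tmmpsf.psf import compute_psf

from conftest import make_chain, random_dag, random_fc


class TestDefinition:
    def test_neutral_gene_has_zero_pi(self, toy_pathway):
        rec = partial_influence(toy_pathway, {"a": 1.0, "b": 2.0}, "a")
        assert rec.pi_log2 == 0.0
        assert rec.observed_fc == 1.0

    def test_activation_chain_pi_is_log2_fc(self):
        p = make_chain("activation", "activation")
        rec = partial_influence(p, {"g0": 2.0, "g1": 1.0, "g2": 1.0}, "g0")
        assert rec.pi_log2 == pytest.approx(1.0)

    def test_overexpressed_inhibitor_has_negative_pi(self):
        p = make_chain("inhibition")
        rec = partial_influence(p, {"g0": 4.0, "g1": 1.0}, "g0")
        assert rec.pi_log2 == pytest.approx(-2.0)

    def test_unknown_gene_rejected(self, toy_pathway):
        with pytest.raises(KeyError):
            partial_influence(toy_pathway, {"a": 1.0, "b": 1.0}, "nope")

    def test_unknown_target_rejected(self, toy_pathway):
        with pytest.raises(KeyError):
            partial_influence(toy_pathway, {"a": 1.0, "b": 1.0}, "a", target="nope")


class TestEngineIdentity:
    @pytest.mark.parametrize("name", ["alt_pathway", "tel_pathway"])
    def test_sink_ratio_equals_two_to_the_pi(self, name, request):
        """sink_raw(observed) / sink_raw(gene neutralized) = 2**pi_log2."""
        pathway = request.getfixturevalue(name)
        rng = random.Random(17)
        for _ in range(5):
            fc = {g: 2.0 ** rng.uniform(-2, 2) for g in pathway.gene_ids()}
            observed = compute_psf(pathway, fc).sink_raw
            for gene in pathway.gene_ids():
                neutralized = neutralize_and_score(pathway, fc, [gene]).sink_raw
                pi = partial_influence(pathway, fc, gene).pi_log2
                assert observed / neutralized == pytest.approx(2.0**pi, rel=1e-12)

    def test_no_path_means_zero_pi(self):
        from tmmpsf.pathway import Pathway, PathwayEdge, PathwayNode

        p = Pathway(
            name="forked",
            nodes=[
                PathwayNode(id="a", node_type="gene"),
                PathwayNode(id="b", node_type="gene"),
                PathwayNode(id="mid", node_type="process"),
                PathwayNode(id="s", node_type="sink"),
            ],
            edges=[
                PathwayEdge("a", "mid"),
                PathwayEdge("mid", "s"),
                PathwayEdge("b", "s"),
            ],
            sink="s",
        )
        # b's influence on 'mid' must be exactly zero: no path
        rec = partial_influence(p, {"a": 3.0, "b": 5.0}, "b", target="mid")
        assert rec.pi_log2 == 0.0


class TestSignLaw:
    def test_parity_determines_pi_sign(self):
        """Even inhibition parity: sign(PI) == sign(log2 FC); odd flips it."""
        from test_psf_engine import _path_parities

        rng = random.Random(29)
        checked = 0
        for _ in range(40):
            p = random_dag(rng)
            fc = random_fc(rng, p)
            for gene in p.gene_ids():
                parities = _path_parities(p, gene, p.sink)
                if len(parities) != 1 or abs(fc[gene] - 1.0) < 1e-9:
                    continue
                pi = partial_influence(p, fc, gene).pi_log2
                fc_up = fc[gene] > 1.0
                if parities == {0}:
                    assert (pi >= 0) == fc_up or pi == 0.0
                else:
                    assert (pi <= 0) == fc_up or pi == 0.0
                checked += 1
        assert checked > 50


class TestProfiles:
    def test_neutral_sample_profile_is_all_zero(self, tel_pathway):
        ones = {g: 1.0 for g in tel_pathway.gene_ids()}
        assert all(r.pi_log2 == 0.0 for r in pi_profile(tel_pathway, ones))

    def test_suppressed_htr_genes_rank_most_negative(self, tel_pathway):
        """Genes knocked to FC 0.25 in the hTR branch dominate the bottom of
        the profile, mirroring the NAF1/WRAP53/PARN mechanism."""
        fc = {g: 1.0 for g in tel_pathway.gene_ids()}
        suppressed = {"NAF1", "WRAP53", "PARN"}
        for g in suppressed:
            fc[g] = 0.25
        profile = pi_profile(tel_pathway, fc)
        bottom = {r.gene for r in profile[:3]}
        assert bottom == suppressed
        assert all(r.pi_log2 < 0 for r in profile[:3])

    def test_profile_is_deterministic(self, alt_pathway):
        rng = random.Random(3)
        fc = {g: 2.0 ** rng.uniform(-1, 1) for g in alt_pathway.gene_ids()}
        first = [(r.gene, r.pi_log2) for r in pi_profile(alt_pathway, fc)]
        second = [(r.gene, r.pi_log2) for r in pi_profile(alt_pathway, fc)]
        assert first == second

    def test_profile_matches_brute_force_neutralization(self, tel_pathway):
        import math

        rng = random.Random(8)
        fc = {g: 2.0 ** rng.uniform(-1.5, 1.5) for g in tel_pathway.gene_ids()}
        observed = compute_psf(tel_pathway, fc).sink_raw
        expected = {}
        for gene in tel_pathway.gene_ids():
            vec = dict(fc)
            vec[gene] = 1.0
            expected[gene] = math.log2(observed / compute_psf(tel_pathway, vec).sink_raw)
        for rec in pi_profile(tel_pathway, fc):
            assert rec.pi_log2 == pytest.approx(expected[rec.gene], abs=1e-12)


class TestWhatIf:
    def test_empty_set_is_identity(self, tel_pathway):
        rng = random.Random(4)
        fc = {g: 2.0 ** rng.uniform(-1, 1) for g in tel_pathway.gene_ids()}
        assert neutralize_and_score(tel_pathway, fc, []).sink_raw == pytest.approx(
            compute_psf(tel_pathway, fc).sink_raw
        )

    def test_neutralizing_all_genes_gives_zero_activity(self, alt_pathway):
        rng = random.Random(5)
        fc = {g: 2.0 ** rng.uniform(-1, 1) for g in alt_pathway.gene_ids()}
        r = neutralize_and_score(alt_pathway, fc, alt_pathway.gene_ids())
        assert r.activity_log2 == 0.0

    def test_rescuing_a_suppressor_switches_the_pathway_on(self, tel_pathway):
        """A single strong suppressor pushes activity below 0; neutralizing it
        flips the call, given mild activation elsewhere."""
        fc = {g: 1.0 for g in tel_pathway.gene_ids()}
        fc["PARN"] = 0.1
        for g in ("TERT", "KPNA1"):
            fc[g] = 1.5
        before = compute_psf(tel_pathway, fc).activity_log2
        after = neutralize_and_score(tel_pathway, fc, ["PARN"]).activity_log2
        assert before < 0 < after

    def test_unknown_gene_rejected(self, tel_pathway):
        with pytest.raises(KeyError):
            neutralize_and_score(tel_pathway, {}, ["NOT_A_GENE"])


class TestMeanSample:
    def _fcm(self, data: dict) -> FoldChangeMatrix:
        return FoldChangeMatrix(values=pd.DataFrame(data))

    def test_single_sample_equals_profile(self, tel_pathway):
        rng = random.Random(6)
        vec = {g: 2.0 ** rng.uniform(-1, 1) for g in tel_pathway.gene_ids()}
        fcm = self._fcm({"s1": pd.Series(vec)})
        mean_records = mean_sample_pi(tel_pathway, fcm)
        direct = pi_profile(tel_pathway, vec)
        assert [(r.gene, r.pi_log2) for r in mean_records] == [
            (r.gene, pytest.approx(r.pi_log2)) for r in direct
        ]

    def test_opposite_shifts_cancel_in_the_mean(self, tel_pathway):
        base = {g: 1.0 for g in tel_pathway.gene_ids()}
        s1, s2 = dict(base), dict(base)
        s1["TERT"], s2["TERT"] = 0.5, 1.5
        fcm = self._fcm({"s1": pd.Series(s1), "s2": pd.Series(s2)})
        records = {r.gene: r.pi_log2 for r in mean_sample_pi(tel_pathway, fcm)}
        assert records["TERT"] == 0.0

    def test_all_ones_matrix_gives_zero_profile(self, tel_pathway):
        ones = {g: 1.0 for g in tel_pathway.gene_ids()}
        fcm = self._fcm({"s1": pd.Series(ones), "s2": pd.Series(ones)})
        assert all(r.pi_log2 == 0.0 for r in mean_sample_pi(tel_pathway, fcm))

    def test_empty_matrix_rejected(self, tel_pathway):
        with pytest.raises(ValueError, match="empty"):
            mean_sample_pi(tel_pathway, FoldChangeMatrix(values=pd.DataFrame()))
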
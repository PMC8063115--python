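"""AS event enumeration, PSI quantification, and differential splicing."""

import numpy as np
import pandas as pd
import pytest

import cosplice as cs

from conftest import make_gene


def _exons(*ivs):
    return list(ivs)


class TestEnumerate:
    def test_exon_skipping(self):
        inc = _exons((0, 100), (200, 300), (400, 500))
        exc = _exons((0, 100), (400, 500))
        g = make_gene("g", "+", [inc, exc])
        events = cs.enumerate_as_events([g])
        assert len(events) == 1
        ev = events[0]
        assert ev.etype == "ES"
        assert ev.inclusion == frozenset({"g.1"})
        assert ev.exclusion == frozenset({"g.2"})

    def test_retained_intron(self):
        spliced = _exons((0, 100), (200, 300))
        retained = _exons((0, 300))
        g = make_gene("g", "+", [spliced, retained])
        events = cs.enumerate_as_events([g])
        assert [e.etype for e in events] == ["RI"]
        assert events[0].inclusion == frozenset({"g.2"})  # intron-retaining

    @pytest.mark.parametrize("strand,short_first,expected", [
        ("+", True, "A5SS"),  # donor shift on + strand
        ("-", True, "A3SS"),  # same genomic change is the acceptor on -
    ])
    def test_alternative_donor_acceptor(self, strand, short_first, expected):
        a = _exons((0, 100), (200, 300))
        b = _exons((0, 140), (200, 300))  # first exon extended into intron
        g = make_gene("g", strand, [a, b])
        events = cs.enumerate_as_events([g])
        assert [e.etype for e in events] == [expected]
        assert events[0].inclusion == frozenset({"g.2"})  # shorter intron

    def test_single_isoform_no_events(self):
        g = make_gene("g", "+", [_exons((0, 100), (200, 300))])
        assert cs.enumerate_as_events([g]) == []

    def test_all_four_types_hand_enumeration(self):
        genes = [
            make_gene("gES", "+", [
                _exons((0, 100), (200, 300), (400, 500)),
                _exons((0, 100), (400, 500)),
            ]),
            make_gene("gRI", "-", [
                _exons((0, 100), (200, 300)),
                _exons((0, 300)),
            ]),
            make_gene("gA5", "+", [
                _exons((0, 100), (200, 300)),
                _exons((0, 130), (200, 300)),
            ]),
            make_gene("gA3", "+", [
                _exons((0, 100), (200, 300)),
                _exons((0, 100), (170, 300)),
            ]),
        ]
        events = cs.enumerate_as_events(genes)
        by_gene = {e.gene_id: e.etype for e in events}
        assert by_gene == {"gES": "ES", "gRI": "RI", "gA5": "A5SS", "gA3": "A3SS"}

    def test_simulated_genome_event_structure(self):
        """Events recovered from the simulator genome are structurally
        consistent: exclusion isoforms carry the defining intron, inclusion
        isoforms the inclusion form."""
        sim = cs.generate_genome(cs.SimulationConfig(n_genes=10), seed=21)
        events = cs.enumerate_as_events(sim.genes)
        assert {e.etype for e in events} == {"ES", "RI", "A5SS", "A3SS"}
        tx = {
            t.transcript_id: t for g in sim.genes for t in g.transcripts
        }
        for ev in events:
            assert not ev.inclusion & ev.exclusion
            if ev.etype == "RI":
                s, e = ev.coords
                for tid in ev.exclusion:
                    assert (s, e) in tx[tid].introns
                for tid in ev.inclusion:
                    assert any(xs < s and e < xe for xs, xe in tx[tid].exons)
            if ev.etype == "ES":
                a, xs, xe, b = ev.coords
                for tid in ev.exclusion:
                    assert (a, b) in tx[tid].introns
                for tid in ev.inclusion:
                    assert (xs, xe) in tx[tid].exons


class TestComputePSI:
    def _event(self):
        return cs.ASEvent("e", "ES", "g", frozenset({"t1", "t2"}),
                          frozenset({"t3"}), (0,))

    def test_worked_example(self):
        tpm = pd.Series({"t1": 2.0, "t2": 1.0, "t3": 1.0})
        out = cs.compute_psi([self._event()], tpm)
        assert out["psi"].iloc[0] == pytest.approx(0.75)

    def test_exclusion_only(self):
        tpm = pd.Series({"t1": 0.0, "t2": 0.0, "t3": 5.0})
        assert cs.compute_psi([self._event()], tpm)["psi"].iloc[0] == 0.0

    def test_all_zero_is_na(self):
        tpm = pd.Series({"t1": 0.0, "t2": 0.0, "t3": 0.0})
        assert np.isnan(cs.compute_psi([self._event()], tpm)["psi"].iloc[0])

    def test_rescale_invariance_and_oracle(self, rng):
        events = [self._event()]
        tpm = pd.Series(rng.uniform(0, 10, 3), index=["t1", "t2", "t3"])
        psi = cs.compute_psi(events, tpm)["psi"].iloc[0]
        psi_scaled = cs.compute_psi(events, tpm * 7.3)["psi"].iloc[0]
        naive = (tpm["t1"] + tpm["t2"]) / tpm.sum()  # spreadsheet recomputation
        assert psi == pytest.approx(naive, abs=1e-12)
        assert psi_scaled == pytest.approx(psi, abs=1e-12)

    def test_es_complementarity(self):
        """Swapping inclusion and exclusion definitions gives PSI summing
        to exactly 1 in a two-isoform gene."""
        ev = cs.ASEvent("e", "ES", "g", frozenset({"t1"}), frozenset({"t2"}), (0,))
        flipped = cs.ASEvent("ec", "ES", "g", frozenset({"t2"}), frozenset({"t1"}), (0,))
        tpm = pd.Series({"t1": 3.0, "t2": 5.0})
        out = cs.compute_psi([ev, flipped], tpm)
        assert out["psi"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_activity_gate(self):
        ev = self._event()
        tpm = pd.DataFrame(
            {"s1": [5, 5, 0.5], "s2": [5, 5, 0.5], "s3": [5, 5, 0.5]},
            index=["t1", "t2", "t3"],
        )
        assert cs.filter_active_events([ev], tpm) == []  # t3 never active
        tpm.loc["t3"] = 2.0
        assert cs.filter_active_events([ev], tpm) == [ev]


class TestCorrelate:
    def _tables(self, psi_vals):
        events = [
            cs.ASEvent(f"e{j}", "RI", "g", frozenset({"a"}), frozenset({"b"}), (j,))
            for j in range(len(psi_vals))
        ]
        df = pd.DataFrame({
            "event_id": [e.event_id for e in events],
            "sample_id": "s",
            "psi": psi_vals,
        })
        return events, df

    def test_identical_rho_one(self):
        events, df = self._tables([0.1, 0.5, 0.9, 0.3])
        out = cs.correlate_psi(df, df.copy(), events)
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_reversed_rho_minus_one(self):
        events, a = self._tables([0.1, 0.5, 0.9, 0.3])
        b = a.copy()
        b["psi"] = 1 - b["psi"]
        out = cs.correlate_psi(a, b, events)
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_rho_decreases_with_noise(self, rng):
        truth = rng.uniform(0, 1, 200)
        events, a = self._tables(truth)
        rhos = []
        for sd in (0.01, 0.1, 0.4):
            b = a.copy()
            b["psi"] = np.clip(truth + rng.normal(0, sd, 200), 0, 1)
            rhos.append(cs.correlate_psi(a, b, events)["rho"].iloc[0])
        assert rhos[0] > rhos[1] > rhos[2]

    def test_too_few_shared_error(self):
        events, a = self._tables([0.5, 0.4])
        with pytest.raises(ValueError):
            cs.correlate_psi(a, a.copy(), events)


class TestDifferentialAS:
    def test_identical_replicates(self):
        a = pd.DataFrame({"r1": [0.5], "r2": [0.5], "r3": [0.5]}, index=["e"])
        out = cs.differential_as(a, a.copy())
        assert out["delta_psi"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == 1.0
        assert not out["significant"].iloc[0]

    def test_exact_permutation_floor_3v3(self):
        """Maximal separation at 3 vs 3 replicates: the exact two-sided
        label-permutation p is its floor 2/20 = 0.1."""
        a = pd.DataFrame([[0.9, 0.9, 0.9]], index=["e"], columns=["r1", "r2", "r3"])
        b = pd.DataFrame([[0.1, 0.1, 0.1]], index=["e"], columns=["r1", "r2", "r3"])
        out = cs.differential_as(a, b, method="permutation")
        assert out["p_value"].iloc[0] == pytest.approx(2 / 20)
        assert out["delta_psi"].iloc[0] == pytest.approx(0.8)

    def test_permutation_super_uniform_under_null(self):
        """Null permutation p-values are super-uniform:
        P(p <= alpha) <= alpha (up to binomial noise)."""
        a = cs.simulate_psi_replicates(np.full(300, 0.5), 3, 0.05, seed=31)
        b = cs.simulate_psi_replicates(np.full(300, 0.5), 3, 0.05, seed=32)
        out = cs.differential_as(a, b, method="permutation")
        for alpha in (0.1, 0.2, 0.5):
            assert (out["p_value"] <= alpha).mean() <= alpha + 0.05

    def test_na_replicates_excluded(self):
        a = pd.DataFrame({"r1": [0.5, np.nan], "r2": [0.5, 0.4]}, index=["e1", "e2"])
        b = pd.DataFrame({"r1": [0.5, 0.2], "r2": [0.5, 0.3]}, index=["e1", "e2"])
        out = cs.differential_as(a, b)
        assert list(out.index) == ["e1"]

    def test_double_cutoff_rule(self):
        # large delta with inconsistent replicates: fails the p gate
        a = pd.DataFrame([[0.9, 0.1, 0.9]], index=["e"], columns=list("xyz"))
        b = pd.DataFrame([[0.2, 0.8, 0.2]], index=["e"], columns=list("xyz"))
        out = cs.differential_as(a, b)
        assert not out["significant"].iloc[0]


class TestOverlap:
    def _calls(self, sig, deltas):
        return pd.DataFrame(
            {"delta_psi": deltas, "p_value": 0.01,
             "significant": sig},
            index=[f"e{j}" for j in range(len(sig))],
        )

    def test_identical_sets(self):
        calls = self._calls([True, True, False, False], [0.4, 0.3, 0.05, -0.2])
        res = cs.overlap_calls(calls, calls.copy())
        assert (res.n_a_only, res.n_shared, res.n_b_only) == (0, 2, 0)
        assert res.rho_all == pytest.approx(1.0)

    def test_disjoint_sets(self):
        a = self._calls([True, False, False, False], [0.4, 0.0, 0.0, 0.0])
        b = self._calls([False, True, False, False], [0.0, 0.4, 0.1, -0.1])
        res = cs.overlap_calls(a, b)
        assert res.n_shared == 0
        assert res.n_a_only == 1 and res.n_b_only == 1

    def test_posttranscriptional_divergence(self, rng):
        """When mature dPSI only partly tracks nascent dPSI, the shared
        significant fraction and cross-assay correlation drop below the
        within-assay ideal."""
        truth = rng.normal(0, 0.25, 300)
        mature = 0.4 * truth + rng.normal(0, 0.2, 300)  # partly posttranscriptional
        a_1 = cs.simulate_psi_replicates(0.5 + truth / 2, 3, 0.03, seed=61)
        a_2 = cs.simulate_psi_replicates(0.5 - truth / 2, 3, 0.03, seed=62)
        b_1 = cs.simulate_psi_replicates(0.5 + mature / 2, 3, 0.03, seed=63)
        b_2 = cs.simulate_psi_replicates(0.5 - mature / 2, 3, 0.03, seed=64)
        calls_a = cs.differential_as(a_1, a_2, seed=1)
        calls_b = cs.differential_as(b_1, b_2, seed=1)
        res = cs.overlap_calls(calls_a, calls_b)
        n_sig_a = int(calls_a["significant"].sum())
        assert 0 < res.n_shared < n_sig_a
        assert res.rho_all < 0.9
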
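"""Fisher's exact machinery and its two applications (TOP motifs, GO terms)."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import gammaln

import polyeff as pe
from polyeff.enrichment import ContingencyTable, fisher_exact


def log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_oracle(a, b, c, d, sided):
    """Full enumeration of all tables with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return math.exp(
            log_choose(row1, x)
            + log_choose(n - row1, col1 - x)
            - log_choose(n, col1)
        )

    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    p_obs = prob(a)
    if sided == "greater":
        return sum(prob(x) for x in range(a, hi + 1))
    return sum(
        p for x in range(lo, hi + 1)
        if (p := prob(x)) <= p_obs * (1 + 1e-7)
    )


class TestFisherExact:
    def test_balanced_table_is_null(self):
        t = ContingencyTable(1, 1, 1, 1)
        assert fisher_exact(t, "two_sided") == pytest.approx(1.0)
        # upper tail of a=1 with margins 2/2 in n=4: 1 - 1/6
        assert fisher_exact(t, "greater") == pytest.approx(5 / 6)

    def test_extreme_table_enumerates_to_2_over_252(self):
        """Margins 5/5: only the two diagonal tables are as unlikely."""
        assert fisher_exact(ContingencyTable(5, 0, 0, 5), "two_sided") == (
            pytest.approx(2 / 252)
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    @pytest.mark.parametrize("sided", ["two_sided", "greater"])
    def test_matches_full_enumeration_on_random_tables(self, sided):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0, 31, size=4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact(ContingencyTable(a, b, c, d), sided)
            assert p == pytest.approx(fisher_oracle(a, b, c, d, sided), abs=1e-10)

    def test_greater_tail_is_hypergeometric_survival(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact(ContingencyTable(a, b, c, d), "greater")
            expected = sps.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c)
            assert p == pytest.approx(expected, abs=1e-10)

    def test_odds_ratio_edge_cases(self):
        assert ContingencyTable(2, 3, 4, 5).odds_ratio == pytest.approx(10 / 12)
        assert ContingencyTable(2, 0, 4, 5).odds_ratio == math.inf
        assert math.isnan(ContingencyTable(0, 0, 4, 0).odds_ratio)


def _classification_from_groups(group_of: dict[str, int]):
    from polyeff.classify import GROUP_TABLE
    genes = sorted(group_of)
    tcs = [GROUP_TABLE[group_of[g]][0] for g in genes]
    tls = [GROUP_TABLE[group_of[g]][1] for g in genes]
    return pe.RegulationClassification.from_statuses(genes, tcs, tls)


class TestTopEnrichment:
    def test_planted_enrichment_detected_in_group_1(self):
        """Motif probability 0.5 in TC:up/TL:up vs 0.05 elsewhere is flagged
        in >= 95% of 100 runs.  Overrepresentation (one-sided) stays quiet in
        every other group in >= 80% of runs; two-sided tests legitimately
        detect the induced *depletion* of other groups, so quietness is a
        one-sided property."""
        from polyeff.classify import group_name

        rng = np.random.default_rng(101)
        hits_g1, false_hits = 0, {g: 0 for g in range(2, 9)}
        n_runs = 100
        for _ in range(n_runs):
            group_of, motif = {}, {}
            for i in range(500):
                gid = int(rng.integers(1, 9))
                gene = f"g{i}"
                group_of[gene] = gid
                motif[gene] = bool(rng.random() < (0.5 if gid == 1 else 0.05))
            cls = _classification_from_groups(group_of)
            results = {r.unit_id: r for r in pe.top_enrichment(cls, motif)}
            if results["TC:up/TL:up"].significant:
                hits_g1 += 1
            greater = {
                r.unit_id: r
                for r in pe.top_enrichment(cls, motif, sided="greater")
            }
            for g in range(2, 9):
                if greater[group_name(g)].significant:
                    false_hits[g] += 1
        assert hits_g1 >= 0.95 * n_runs
        for g, n_false in false_hits.items():
            assert n_runs - n_false >= 0.80 * n_runs

    def test_uniform_motif_probability_controls_type_I_error(self):
        rng = np.random.default_rng(202)
        n_runs, alpha = 200, 0.05
        false = 0
        for _ in range(n_runs):
            group_of = {f"g{i}": int(rng.integers(1, 9)) for i in range(400)}
            motif = {g: bool(rng.random() < 0.2) for g in group_of}
            cls = _classification_from_groups(group_of)
            results = pe.top_enrichment(cls, motif)
            false += sum(r.significant for r in results)
        rate = false / (n_runs * 8)
        # binomial error band around alpha over 1600 tests
        se = math.sqrt(alpha * (1 - alpha) / (n_runs * 8))
        assert rate <= alpha + 4 * se

    def test_all_genes_bearing_makes_every_test_null(self):
        group_of = {f"g{i}": 1 + i % 8 for i in range(80)}
        motif = {g: True for g in group_of}
        cls = _classification_from_groups(group_of)
        for r in pe.top_enrichment(cls, motif):
            assert r.table.b == 0 and r.table.d == 0
            assert r.p_value == pytest.approx(1.0)

    def test_margins_and_exclusion_of_genes_without_utr(self):
        group_of = {f"g{i}": 1 + i % 8 for i in range(80)}
        motif = {g: i % 3 == 0 for i, g in enumerate(sorted(group_of))}
        del motif[sorted(group_of)[0]]  # one gene without UTR
        cls = _classification_from_groups(group_of)
        results = pe.top_enrichment(cls, motif)
        n_scoped = len(motif)
        n_bearing = sum(motif.values())
        for r in results:
            t = r.table
            assert t.a + t.b + t.c + t.d == n_scoped
            assert t.a + t.c == n_bearing


class TestGoEnrichment:
    @staticmethod
    def _flat_ontology(n_terms, annotations):
        terms = {"GO:0000001": pe.TermRecord("GO:0000001", "root", "BP")}
        for i in range(2, n_terms + 1):
            tid = f"GO:{i:07d}"
            terms[tid] = pe.TermRecord(tid, f"t{i}", "BP", frozenset({"GO:0000001"}))
        return pe.GeneOntology(terms=terms, annotations=annotations)

    def test_term_equal_to_group_attains_the_hypergeometric_minimum(self):
        genes = [f"g{i}" for i in range(12)]
        group = genes[:4]
        ann = {g: frozenset({"GO:0000002"}) for g in group}
        ann.update({g: frozenset({"GO:0000003"}) for g in genes[4:]})
        onto = self._flat_ontology(3, ann)
        frame = pe.go_enrichment({1: group, 2: genes[4:]}, onto, namespace="BP")
        row = frame[(frame.group_id == 1) & (frame.term_id == "GO:0000002")].iloc[0]
        assert row.p_value == pytest.approx(1 / math.comb(12, 4))

    def test_term_covering_universe_is_null(self):
        genes = [f"g{i}" for i in range(10)]
        ann = {g: frozenset({"GO:0000002"}) for g in genes}
        onto = self._flat_ontology(2, ann)
        frame = pe.go_enrichment({1: genes[:3], 2: genes[3:]}, onto)
        # propagated root and the term both cover everything
        assert np.allclose(frame["p_value"], 1.0)

    def test_empty_universe_errors(self):
        onto = self._flat_ontology(2, {})
        with pytest.raises(ValueError, match="universe"):
            pe.go_enrichment({1: ["g1"]}, onto)

    def test_no_multiplicity_adjustment_is_applied(self):
        genes = [f"g{i}" for i in range(30)]
        onto, _ = pe.simulate_ontology(genes, n_terms=20, seed=7)
        frame = pe.go_enrichment({1: genes[:10], 2: genes[10:]}, onto)
        # significance is a raw-p threshold, so it must equal p <= 0.05 exactly
        assert (frame["significant"] == (frame["p_value"] <= 0.05)).all()

    def test_ancestor_counts_dominate_descendants(self):
        genes = [f"g{i}" for i in range(40)]
        onto, _ = pe.simulate_ontology(genes, n_terms=25, seed=8)
        frame = pe.go_enrichment({1: genes[:15], 2: genes[15:]}, onto)
        counts = {
            (g, t): a for g, t, a in zip(frame.group_id, frame.term_id, frame.a)
        }
        for tid in onto.terms:
            for anc in onto.ancestors(tid):
                for gid in (1, 2):
                    if (gid, tid) in counts and (gid, anc) in counts:
                        assert counts[(gid, anc)] >= counts[(gid, tid)]

    def test_planted_terms_outrank_background(self):
        """Enriched terms land in the top decile of p-values in >=90% of runs."""
        genes = [f"g{i}" for i in range(500)]
        target = genes[:100]
        wins, n_runs = 0, 40
        for seed in range(n_runs):
            onto, enriched = pe.simulate_ontology(
                genes, n_terms=30, enriched_term_fraction=0.05,
                target_group_genes=target, background_p=0.05, enriched_p=0.25,
                seed=seed,
            )
            frame = pe.go_enrichment(
                {1: target, 2: genes[100:]}, onto, namespace="BP"
            )
            g1 = frame[frame.group_id == 1].reset_index(drop=True)
            cutoff = max(1, int(np.ceil(len(g1) / 10)))
            top_terms = set(g1.nsmallest(cutoff, "p_value")["term_id"])
            if set(enriched) <= top_terms:
                wins += 1
        assert wins >= 0.90 * n_runs
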
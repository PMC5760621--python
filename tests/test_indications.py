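"""Mode-aware drug-disease linking and its evaluation."""

import numpy as np
import pandas as pd
import pytest

from sigtarget import (
    ConfigurationError,
    InteractionTable,
    build_disease_profile,
    build_drug_profile,
    evaluate_indications,
    link_drugs_to_diseases,
    threshold_top_fraction,
)


class TestThresholdTopFraction:
    def make_scores(self, rng, n_drugs=20, n_prot=5):
        return pd.DataFrame(
            rng.normal(size=(n_drugs, n_prot)),
            index=[f"d{i}" for i in range(n_drugs)],
            columns=[f"p{j}" for j in range(n_prot)],
        )

    def test_five_percent_of_100_pairs(self, rng):
        top = threshold_top_fraction(self.make_scores(rng), 0.05, "inhibition")
        assert len(top) == 5

    def test_fraction_one_selects_all(self, rng):
        scores = self.make_scores(rng)
        assert len(threshold_top_fraction(scores, 1.0, "inhibition")) == scores.size

    def test_matches_full_sort_oracle(self, rng):
        scores = self.make_scores(rng, 4, 5)
        top = threshold_top_fraction(scores, 0.05, "activation")  # ceil(1) = 1 pair
        best = scores.stack().idxmax()
        assert top == {(best[0], best[1], "activation")}

    def test_ties_broken_lexicographically(self):
        scores = pd.DataFrame(
            [[1.0, 1.0], [1.0, 1.0]], index=["db", "da"], columns=["p2", "p1"]
        )
        top = threshold_top_fraction(scores, 0.25, "inhibition")
        assert top == {("da", "p1", "inhibition")}

    def test_empty_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            threshold_top_fraction(pd.DataFrame(), 0.05, "inhibition")


class TestBuildDrugProfile:
    known = InteractionTable(
        {("d1", "pA", "inhibition"), ("d1", "pB", "activation"),
         ("d2", "pC", "inhibition")},
        ("d1", "d2"),
        ("pA", "pB", "pC"),
    )

    def test_known_only(self):
        profile = build_drug_profile("d1", self.known)
        assert profile.keys() == {("pA", "inhibition"), ("pB", "activation")}
        assert all(v == "known" for v in profile.entries.values())

    def test_known_takes_precedence_on_overlap(self):
        predicted = {("d1", "pA", "inhibition"), ("d1", "pC", "inhibition")}
        profile = build_drug_profile("d1", self.known, predicted)
        assert profile.entries[("pA", "inhibition")] == "known"
        assert profile.entries[("pC", "inhibition")] == "predicted"

    def test_union_counts(self):
        predicted = {("d2", "pA", "activation"), ("d2", "pB", "inhibition"),
                     ("d2", "pB", "activation")}
        profile = build_drug_profile("d2", self.known, predicted)
        assert len(profile.entries) == 4  # 1 known + 3 disjoint predicted


class TestLinkDrugsToDiseases:
    def world(self):
        drugs = {
            "inhib": build_drug_profile(
                "inhib", {("inhib", "P", "inhibition")}
            ),
            "activ": build_drug_profile(
                "activ", {("activ", "P", "activation")}
            ),
            "other": build_drug_profile(
                "other", {("other", "Q", "inhibition")}
            ),
        }
        diseases = {"dz": build_disease_profile("dz", {("P", "inhibition")})}
        return drugs, diseases

    def test_mode_matched_link(self):
        drugs, diseases = self.world()
        preds = {
            (p.drug_id, p.disease_id): p
            for p in link_drugs_to_diseases(drugs, diseases, True)
        }
        assert preds[("inhib", "dz")].linked
        assert not preds[("activ", "dz")].linked

    def test_without_distinction_opposite_mode_links(self):
        drugs, diseases = self.world()
        preds = {
            (p.drug_id, p.disease_id): p
            for p in link_drugs_to_diseases(drugs, diseases, False)
        }
        assert preds[("activ", "dz")].linked
        assert preds[("inhib", "dz")].linked

    def test_disjoint_proteins_never_link(self):
        drugs, diseases = self.world()
        for flag in (True, False):
            preds = {
                (p.drug_id, p.disease_id): p
                for p in link_drugs_to_diseases(drugs, diseases, flag)
            }
            assert not preds[("other", "dz")].linked

    def test_mode_matching_only_removes_links(self, rng):
        """With-distinction linked set is a subset of without-distinction."""
        proteins = [f"p{i}" for i in range(6)]
        modes = ["inhibition", "activation"]
        drugs = {}
        for i in range(12):
            triples = {
                (f"d{i}", proteins[int(rng.integers(6))], modes[int(rng.integers(2))])
                for _ in range(int(rng.integers(1, 4)))
            }
            drugs[f"d{i}"] = build_drug_profile(f"d{i}", triples)
        diseases = {}
        for z in range(5):
            targets = {
                (proteins[int(rng.integers(6))], modes[int(rng.integers(2))])
                for _ in range(int(rng.integers(1, 3)))
            }
            diseases[f"z{z}"] = build_disease_profile(f"z{z}", targets)
        with_modes = {
            (p.drug_id, p.disease_id)
            for p in link_drugs_to_diseases(drugs, diseases, True)
            if p.linked
        }
        without = {
            (p.drug_id, p.disease_id)
            for p in link_drugs_to_diseases(drugs, diseases, False)
            if p.linked
        }
        assert with_modes <= without

    def test_score_independent_of_entry_insertion_order(self):
        t = [("d", "pA", "inhibition"), ("d", "pB", "activation")]
        fwd = build_drug_profile("d", t)
        rev = build_drug_profile("d", list(reversed(t)))
        dz = {"z": build_disease_profile("z", {("pA", "inhibition"), ("pB", "activation")})}
        s1 = link_drugs_to_diseases({"d": fwd}, dz, True)[0].score
        s2 = link_drugs_to_diseases({"d": rev}, dz, True)[0].score
        assert s1 == s2 == 2


def opposite(mode):
    return "activation" if mode == "inhibition" else "inhibition"


class TestEvaluateIndications:
    def test_perfect_scores_give_auc_one(self):
        drugs = {
            "good": build_drug_profile("good", {("good", "P", "inhibition")}),
            "bad": build_drug_profile("bad", {("bad", "Q", "inhibition")}),
        }
        dz = {"z": build_disease_profile("z", {("P", "inhibition")})}
        preds = link_drugs_to_diseases(drugs, dz, True)
        table = evaluate_indications(preds, {("good", "z")})
        assert table.loc[0, "auc"] == pytest.approx(1.0)

    def test_random_world_near_half(self, rng):
        n_drugs, n_dz = 60, 8
        preds = []
        known = set()
        from sigtarget.indications import DrugDiseasePrediction

        for z in range(n_dz):
            for i in range(n_drugs):
                score = int(rng.integers(0, 4))
                preds.append(
                    DrugDiseasePrediction(f"d{i}", f"z{z}", set(), score, score >= 1)
                )
                if rng.random() < 0.3:
                    known.add((f"d{i}", f"z{z}"))
        table = evaluate_indications(preds, known)
        assert table["auc"].mean() == pytest.approx(0.5, abs=0.12)

    def test_mode_distinction_improves_auc_when_modes_matter(self, rng):
        """Half the shared-protein drug-disease pairs act in the wrong mode;
        distinguishing modes separates true from spurious links."""
        n_dz, per_dz = 10, 6
        drugs, diseases, known = {}, {}, set()
        k = 0
        for z in range(n_dz):
            protein, mode = f"P{z}", ("inhibition" if z % 2 else "activation")
            diseases[f"z{z}"] = build_disease_profile(f"z{z}", {(protein, mode)})
            for i in range(per_dz):
                drug = f"d{k}"
                k += 1
                if i < per_dz // 2:  # correct mode: truly indicated
                    drugs[drug] = build_drug_profile(drug, {(drug, protein, mode)})
                    known.add((drug, f"z{z}"))
                else:  # same protein, opposite mode: not indicated
                    drugs[drug] = build_drug_profile(
                        drug, {(drug, protein, opposite(mode))}
                    )
        with_modes = evaluate_indications(
            link_drugs_to_diseases(drugs, diseases, True), known
        )
        without = evaluate_indications(
            link_drugs_to_diseases(drugs, diseases, False), known
        )
        assert with_modes["auc"].mean() > without["auc"].mean()
        assert with_modes["auc"].mean() == pytest.approx(1.0)

    def test_single_class_disease_skipped(self):
        drugs = {"d": build_drug_profile("d", {("d", "P", "inhibition")})}
        dz = {"z": build_disease_profile("z", {("P", "inhibition")})}
        preds = link_drugs_to_diseases(drugs, dz, True)
        table = evaluate_indications(preds, {("d", "z")})
        assert table.empty
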
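import math

import numpy as np
import pytest

from quatbind.data import default_exclusion_list
from quatbind.fixtures import make_affinity_dataset
from quatbind.partition import Ligand, PolymerChain
from quatbind.relevance_affinity import (
    AffinityModel,
    ExclusionList,
    assess_relevance,
    bootstrap_pcc_compare,
    fit_consensus,
    predict_consensus,
    read_affinity_table,
    to_pkd,
)
from quatbind.site_annotation import BindingSite


def _site(n, chain="A"):
    return BindingSite(residues=[(chain, i + 1, "ALA", 3.0) for i in range(n)])


def _small_mol(comp):
    import numpy as np
    from quatbind.structure_io import AtomRecord

    return Ligand(kind="small_molecule", ligand_id=comp, comp_id=comp,
                  atoms=[AtomRecord(1, "C1", "C", comp, "L", 1, "", np.zeros(3),
                                    is_polymer=False)])


@pytest.fixture(scope="module")
def exclusion():
    return ExclusionList(comp_ids={"GOL", "EDO", "SO4", "PEG"})


class TestExclusionList:
    def test_from_file(self, tmp_path):
        f = tmp_path / "list.txt"
        f.write_text("# additives\ngol\nEDO\n\nSO4\n")
        lst = ExclusionList.from_file(f)
        assert lst.comp_ids == {"GOL", "EDO", "SO4"}
        assert lst.checksum

    def test_bad_id_rejected(self):
        with pytest.raises(ValueError):
            ExclusionList(comp_ids={"TOOLONGID"})

    def test_packaged_default_loads(self):
        lst = default_exclusion_list()
        assert "GOL" in lst and len(lst.comp_ids) > 20


class TestAssessRelevance:
    def test_peptide_unconditionally_relevant(self, exclusion):
        pep = Ligand(kind="peptide", ligand_id="peptide",
                     chains=[PolymerChain("P", "protein",
                                          [(i, "ALA") for i in range(1, 6)])])
        v = assess_relevance(pep, None, exclusion)
        assert v.status == "relevant" and v.rule_fired == "peptide_or_nucleic"

    def test_nucleic_unconditionally_relevant(self, exclusion):
        nuc = Ligand(kind="nucleic", ligand_id="dna",
                     chains=[PolymerChain("X", "dna", [(1, "DA")])])
        v = assess_relevance(nuc, None, exclusion)
        assert v.status == "relevant" and v.rule_fired == "peptide_or_nucleic"

    def test_unlisted_molecule_relevant_by_default(self, exclusion):
        v = assess_relevance(_small_mol("XYZ"), _site(2), exclusion)
        assert v.status == "relevant" and v.rule_fired == "not_in_list"

    def test_listed_small_site_irrelevant(self, exclusion):
        v = assess_relevance(_small_mol("GOL"), _site(2), exclusion,
                             min_site_residues=6)
        assert v.status == "irrelevant" and v.rule_fired == "site_size_rule"

    def test_listed_large_site_needs_review_without_abstract(self, exclusion):
        v = assess_relevance(_small_mol("GOL"), _site(8), exclusion)
        assert v.status == "needs_review" and v.rule_fired == "listed_default"

    def test_keyword_rule_promotes(self, exclusion):
        abstract = ("The structure shows that GOL binds in the catalytic pocket. "
                    "Crystals grew in PEG 3350.")
        v = assess_relevance(_small_mol("GOL"), _site(8), exclusion,
                             abstract_text=abstract)
        assert v.status == "relevant" and v.rule_fired == "keyword_rule"

    def test_keyword_needs_cooccurrence(self, exclusion):
        abstract = "GOL was present. The substrate binds elsewhere."
        v = assess_relevance(_small_mol("GOL"), _site(8), exclusion,
                             abstract_text=abstract)
        assert v.status == "needs_review"

    def test_listed_without_site_is_error(self, exclusion):
        with pytest.raises(ValueError, match="binding site"):
            assess_relevance(_small_mol("GOL"), None, exclusion)

    def test_quaternary_site_never_smaller_than_single_chain(self, exclusion):
        # multi-chain pockets only add residues: the quaternary verdict
        # can only see a larger site than any single-chain restriction
        quaternary = BindingSite(residues=[("A", 1, "ALA", 3.0), ("A", 2, "ALA", 3.1),
                                           ("B", 1, "ALA", 3.0), ("B", 2, "ALA", 3.2),
                                           ("B", 3, "ALA", 3.3), ("B", 4, "ALA", 3.4)])
        for chain in ("A", "B"):
            assert quaternary.restricted_to(chain).n_residues <= quaternary.n_residues
        v_quat = assess_relevance(_small_mol("GOL"), quaternary, exclusion,
                                  min_site_residues=6)
        v_single = assess_relevance(_small_mol("GOL"), quaternary.restricted_to("B"),
                                    exclusion, min_site_residues=6)
        assert v_quat.status == "needs_review"  # survives the size rule
        assert v_single.status == "irrelevant"  # discarded on a single chain


class TestAffinityTable:
    def test_kd_2nm(self):
        assert to_pkd("Kd", 2, "nM") == pytest.approx(-math.log10(2e-9))
        assert round(to_pkd("Kd", 2, "nM"), 2) == 8.70

    def test_kd_1m_is_zero(self):
        assert to_pkd("Kd", 1, "M") == 0.0

    @pytest.mark.parametrize("unit,factor", [("M", 1), ("mM", 1e-3), ("uM", 1e-6),
                                             ("nM", 1e-9), ("pM", 1e-12)])
    def test_unit_grid(self, unit, factor):
        assert to_pkd("Ki", 5, unit) == pytest.approx(-math.log10(5 * factor))

    def test_rejects_collected_not_fatal(self, tmp_path):
        f = tmp_path / "aff.tsv"
        f.write_text(
            "pdb_id\tligand_id\tchain\tmeasure\tvalue\tunit\tsource\n"
            "1abc\tLIG\tA\tKd\t2\tnM\tmoad\n"
            "1abd\tLIG\tA\tKd\t2\tfurlongs\tmoad\n"
        )
        accepted, rejects = read_affinity_table(f)
        assert len(accepted) == 1 and len(rejects) == 1
        assert accepted.iloc[0]["pkd"] == pytest.approx(8.699, abs=1e-3)
        assert "furlongs" in rejects.iloc[0]["reject_reason"]

    def test_missing_header_is_error(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("pdb\tvalue\n1abc\t2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_affinity_table(f)


class TestConsensusModel:
    def test_exact_recovery_noise_free(self):
        ds = make_affinity_dataset(n=50, weights=(0.5, 0.3, -0.2), intercept=1.0,
                                   noise_sigma=0.0, seed=3)
        rows = np.column_stack([ds["X"], ds["y"]])
        model = fit_consensus(rows)
        assert model.intercept == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(model.weights, [0.5, 0.3, -0.2], atol=1e-8)

    def test_interpolation(self):
        ds = make_affinity_dataset(n=30, noise_sigma=0.0, seed=4)
        rows = np.column_stack([ds["X"], ds["y"]])
        model = fit_consensus(rows)
        for i in range(30):
            assert predict_consensus(model, ds["X"][i]) == pytest.approx(ds["y"][i],
                                                                         abs=1e-8)

    def test_consensus_pcc_dominates_univariates(self):
        ds = make_affinity_dataset(n=285, weights=(0.5, 0.45, -0.4),
                                   noise_sigma=0.56, seed=7)
        model = fit_consensus(np.column_stack([ds["X"], ds["y"]]))
        for name, pcc in model.pcc_univariate.items():
            assert model.pcc_consensus >= abs(pcc), name

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_consensus(np.ones((5, 4)))

    def test_rank_deficient_design(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        rows = np.column_stack([x, x, x, x])  # perfectly collinear scores
        with pytest.raises(ValueError, match="collinear"):
            fit_consensus(rows)

    def test_predict_requires_all_components(self):
        model = AffinityModel(intercept=6.0, weights=np.zeros(3))
        with pytest.raises(ValueError):
            predict_consensus(model, [1.0, 2.0])

    def test_zero_weight_model_constant(self):
        model = AffinityModel(intercept=6.0, weights=np.zeros(3))
        assert predict_consensus(model, [9.0, -4.0, 2.0]) == 6.0

    def test_prediction_dot_product_oracle(self):
        rng = np.random.default_rng(5)
        model = AffinityModel(intercept=0.7, weights=rng.normal(size=3))
        for _ in range(20):
            x = rng.normal(size=3)
            manual = 0.7 + sum(model.weights[i] * x[i] for i in range(3))
            assert predict_consensus(model, x) == pytest.approx(manual, abs=1e-12)

    def test_dataset_round_trip_via_tsv(self, tmp_path):
        ds = make_affinity_dataset(n=40, noise_sigma=0.0, seed=8, out_dir=tmp_path)
        accepted, rejects = read_affinity_table(ds["affinity_path"])
        assert len(rejects) == 0
        np.testing.assert_allclose(np.sort(accepted["pkd"]), np.sort(ds["y"]), atol=1e-5)


class TestBootstrap:
    def test_identical_predictions_not_significant(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=100)
        pred = y + rng.normal(size=100)
        result = bootstrap_pcc_compare(pred, pred, y, seed=1)
        assert result.delta_mean == 0.0 and not result.significant

    def test_planted_improvement_significant(self):
        ds = make_affinity_dataset(n=285, weights=(0.5, 0.45, -0.4),
                                   noise_sigma=0.56, seed=7)
        model = fit_consensus(np.column_stack([ds["X"], ds["y"]]))
        consensus = np.array([predict_consensus(model, x) for x in ds["X"]])
        single = ds["X"][:, 0]
        result = bootstrap_pcc_compare(consensus, single, ds["y"], n_boot=1000, seed=1)
        assert result.significant and result.delta_mean > 0

    def test_seed_determinism(self):
        ds = make_affinity_dataset(n=100, noise_sigma=0.5, seed=9)
        r1 = bootstrap_pcc_compare(ds["X"][:, 0], ds["X"][:, 1], ds["y"], seed=42)
        r2 = bootstrap_pcc_compare(ds["X"][:, 0], ds["X"][:, 1], ds["y"], seed=42)
        assert (r1.delta_mean, r1.ci_low, r1.ci_high) == (r2.delta_mean, r2.ci_low,
                                                          r2.ci_high)

    def test_seed_stability_overlapping_cis(self):
        ds = make_affinity_dataset(n=285, weights=(0.5, 0.45, -0.4),
                                   noise_sigma=0.56, seed=7)
        model = fit_consensus(np.column_stack([ds["X"], ds["y"]]))
        consensus = np.array([predict_consensus(model, x) for x in ds["X"]])
        single = ds["X"][:, 0]
        r1 = bootstrap_pcc_compare(consensus, single, ds["y"], seed=1)
        r2 = bootstrap_pcc_compare(consensus, single, ds["y"], seed=2)
        assert r1.ci_low < r2.ci_high and r2.ci_low < r1.ci_high

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            bootstrap_pcc_compare(np.ones(50), np.ones(40), np.ones(50))

    def test_min_n(self):
        with pytest.raises(ValueError, match="n >= 30"):
            bootstrap_pcc_compare(np.ones(10), np.ones(10), np.ones(10))
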
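import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors

from delforge.curation import (BBClass, RawCandidate, curate, desalt,
                               kmeans_select, matches_class, morgan_fp,
                               ro2_profile)
from delforge.errors import EmptySetError, ParseError


class TestDesalt:
    def test_largest_fragment(self):
        assert desalt("CC(=O)O.[Na+].[Cl-]") == Chem.CanonSmiles("CC(=O)O")

    def test_single_fragment_identity(self):
        assert desalt("C#Cc1ccccc1") == Chem.CanonSmiles("C#Cc1ccccc1")

    def test_tie_broken_by_canonical_order(self):
        # CCN and CCO have equal heavy-atom counts; "CCN" < "CCO"
        assert desalt("CCO.CCN") == "CCN"
        assert desalt("CCN.CCO") == "CCN"

    def test_parse_error(self):
        with pytest.raises(ParseError):
            desalt("not_a_smiles((")

    def test_neutralizes_simple_charges(self):
        assert desalt("CC(=O)[O-]") == Chem.CanonSmiles("CC(=O)O")
        assert desalt("CC[NH3+]") == Chem.CanonSmiles("CCN")

    def test_accepts_raw_candidate(self):
        cand = RawCandidate(source_id="x", smiles="CC(=O)O.[Na+]")
        assert desalt(cand) == Chem.CanonSmiles("CC(=O)O")

    @given(st.permutations(["CC(=O)O", "[Na+]", "[Cl-]", "O", "CCN"]))
    @settings(max_examples=25, deadline=None)
    def test_fragment_order_independence(self, frags):
        assert desalt(".".join(frags)) == desalt(".".join(sorted(frags)))


class TestRo2Profile:
    def test_mw_over_200_fails_mw_only(self):
        # N,N'-hexamethylene-bis-acetamide: MW ~200.3, polar, HBD 2, HBA 4
        smi = "CC(=O)NCCCCCCNC(=O)C"
        mol = Chem.MolFromSmiles(smi)
        assert Descriptors.MolWt(mol) > 200
        prof = ro2_profile(smi)
        assert not prof.passes
        assert prof.reject_reasons == ("mw",)

    def test_cyclopropane_carboxylic_acid_passes(self):
        prof = ro2_profile("OC(=O)C1CC1")
        assert prof.passes
        assert prof.mw == pytest.approx(86.09, abs=0.01)
        assert prof.hbd == 1
        assert prof.hba == 2
        # independent descriptor oracle for the clogP criterion
        assert Crippen.MolLogP(Chem.MolFromSmiles("OC(=O)C1CC1")) < 2

    def test_hbd_over_2_fails_regardless(self):
        prof = ro2_profile("OCC(O)CO")  # glycerol, HBD 3
        assert not prof.passes
        assert "hbd" in prof.reject_reasons

    def test_reject_reasons_empty_iff_passes(self):
        for smi in ["CC(=O)O", "OCC(O)CO", "CCCCCCCCCCCCCCCC(=O)O"]:
            prof = ro2_profile(smi)
            assert prof.passes == (len(prof.reject_reasons) == 0)


class TestMorganFp:
    def test_determinism(self):
        a = morgan_fp("CC(=O)CC(=O)OC")
        b = morgan_fp(Chem.CanonSmiles("CC(=O)CC(=O)OC"))
        assert np.array_equal(a, b)

    def test_distinct_molecules_differ(self):
        assert not np.array_equal(morgan_fp("C"), morgan_fp("CC"))

    def test_benzene_reference_fingerprint(self):
        # frozen from the legacy GetMorganFingerprintAsBitVect oracle
        fp = morgan_fp("c1ccccc1")
        assert fp.sum() == 3
        assert sorted(np.flatnonzero(fp)) == [64, 389, 849]

    def test_shape_and_dtype(self):
        fp = morgan_fp("CCO", nbits=512)
        assert fp.shape == (512,)
        assert set(np.unique(fp)) <= {0, 1}


def _brute_force_reps(X, k, seed, ids):
    """Independent oracle: same contract as kmeans_select on tiny inputs."""
    from sklearn.cluster import KMeans

    order = sorted(range(len(ids)), key=lambda i: ids[i])
    seen, uniq = set(), []
    for i in order:
        key = X[i].tobytes()
        if key not in seen:
            seen.add(key)
            uniq.append(i)
    Xu = X[uniq]
    if len(uniq) <= k:
        return sorted(ids[i] for i in uniq)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Xu)
    reps = []
    for c in range(k):
        members = [j for j in range(len(uniq)) if km.labels_[j] == c]
        d = [(np.linalg.norm(Xu[j] - km.cluster_centers_[c]), ids[uniq[j]])
             for j in members]
        reps.append(min(d, key=lambda t: (round(t[0], 12), t[1]))[1])
    return sorted(reps)


class TestKmeansSelect:
    def test_n_equals_k_returns_all(self):
        X = np.eye(5, 16)
        sel = kmeans_select(X, k=5, seed=1, ids=list("abcde"))
        assert sorted(sel.representative_ids) == list("abcde")

    def test_duplication_invariance(self):
        rng = np.random.default_rng(4)
        X = (rng.random((6, 16)) < 0.4).astype(float)
        ids = [f"m{i}" for i in range(6)]
        sel1 = kmeans_select(X, k=3, seed=7, ids=ids)
        Xdup = np.vstack([X, X])
        sel2 = kmeans_select(Xdup, k=3, seed=7, ids=ids + [f"z{i}" for i in
                                                           range(6)])
        # duplicates carry higher-sorting ids, so the rep set is unchanged
        assert sorted(sel1.representative_ids) == sorted(
            sel2.representative_ids)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = (rng.random((30, 32)) < 0.3).astype(float)
        ids = [f"m{i:02d}" for i in range(30)]
        sel1 = kmeans_select(X, k=8, seed=3, ids=ids)
        perm = rng.permutation(30)
        sel2 = kmeans_select(X[perm], k=8, seed=3,
                             ids=[ids[i] for i in perm])
        assert sorted(sel1.representative_ids) == sorted(
            sel2.representative_ids)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        X = (rng.random((9, 16)) < 0.4).astype(float)
        ids = [f"m{i}" for i in range(9)]
        sel = kmeans_select(X, k=3, seed=2, ids=ids)
        assert sorted(sel.representative_ids) == _brute_force_reps(
            X, 3, 2, ids)

    def test_n_below_k_warns(self):
        X = np.eye(3, 8)
        with pytest.warns(UserWarning, match="own representative"):
            sel = kmeans_select(X, k=10, seed=0, ids=list("abc"))
        assert sorted(sel.representative_ids) == list("abc")

    def test_representative_in_own_cluster(self):
        rng = np.random.default_rng(8)
        X = (rng.random((20, 16)) < 0.4).astype(float)
        ids = [f"m{i:02d}" for i in range(20)]
        sel = kmeans_select(X, k=5, seed=1, ids=ids)
        clusters_of_reps = {sel.cluster_assignments[r]
                           for r in sel.representative_ids}
        assert clusters_of_reps == set(range(5))


ACIDS_OK = ["CC(=O)O", "CCC(=O)O", "OC(=O)C1CC1", "OC(=O)c1ccccc1",
            "OC(=O)CO", "OC(=O)CCC", "OC(=O)C(C)C", "OC(=O)C1CCC1"]
ACIDS_RO2_FAIL = ["OC(=O)CCCCCCCCCCCCCCCC"]  # palmitic-like, MW/clogP out
NOT_ACIDS = ["C#CC", "CCO"]
CROSS_REACTIVE = ["OC(=O)CC#C", "OC(=O)CCN=[N+]=[N-]"]


class TestCurate:
    def _cands(self, smiles):
        return [RawCandidate(source_id=f"c{i}", smiles=s)
                for i, s in enumerate(smiles)]

    def test_full_pipeline(self):
        cands = self._cands(ACIDS_OK + ACIDS_RO2_FAIL + NOT_ACIDS
                            + CROSS_REACTIVE + ["bad(("])
        res = curate(cands, BBClass.CARBOXYLIC_ACID, k=5, seed=0)
        assert len(res.blocks) == 5
        counts = res.report["counts"]
        assert counts["parse_error"] == 1
        assert counts["class_fail"] == len(NOT_ACIDS) + len(CROSS_REACTIVE)
        assert counts["ro2_fail"] == 1
        assert counts["ro2_pass"] == len(ACIDS_OK)

    def test_representative_validity(self):
        res = curate(self._cands(ACIDS_OK), BBClass.CARBOXYLIC_ACID,
                     k=4, seed=0)
        for b in res.blocks:
            assert b.ro2.passes
            assert matches_class(b.smiles, BBClass.CARBOXYLIC_ACID)
            assert b.fp.shape == (1024,)

    def test_all_ro2_fail_raises_named_stage(self):
        with pytest.raises(EmptySetError) as exc:
            curate(self._cands(ACIDS_RO2_FAIL), BBClass.CARBOXYLIC_ACID,
                   k=5, seed=0)
        assert exc.value.stage == "ro2"

    def test_all_class_fail_raises_named_stage(self):
        with pytest.raises(EmptySetError) as exc:
            curate(self._cands(NOT_ACIDS), BBClass.CARBOXYLIC_ACID,
                   k=5, seed=0)
        assert exc.value.stage == "class"

    def test_k_larger_than_survivors_returns_all_with_warning(self):
        with pytest.warns(UserWarning):
            res = curate(self._cands(ACIDS_OK), BBClass.CARBOXYLIC_ACID,
                         k=50, seed=0)
        assert len(res.blocks) == len(ACIDS_OK)

    def test_determinism(self):
        cands = self._cands(ACIDS_OK)
        r1 = curate(cands, BBClass.CARBOXYLIC_ACID, k=4, seed=3)
        r2 = curate(cands, BBClass.CARBOXYLIC_ACID, k=4, seed=3)
        assert [b.smiles for b in r1.blocks] == [b.smiles for b in r2.blocks]
        assert [b.bb_id for b in r1.blocks] == [b.bb_id for b in r2.blocks]

    def test_filter_monotonicity(self):
        # adding a candidate never removes a previously passing one
        base = self._cands(ACIDS_OK[:4])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            before = {b.smiles for b in curate(
                base, BBClass.CARBOXYLIC_ACID, k=50, seed=0).blocks}
            after = {b.smiles for b in curate(
                base + self._cands(["OC(=O)CC(C)C"]),
                BBClass.CARBOXYLIC_ACID, k=50, seed=0).blocks}
        assert before <= after

    def test_class_and_ro2_filters_commute(self):
        smiles = [desalt(c) for c in
                  self._cands(ACIDS_OK + ACIDS_RO2_FAIL + NOT_ACIDS)]
        cls_then_ro2 = [s for s in smiles
                        if matches_class(s, BBClass.CARBOXYLIC_ACID)]
        cls_then_ro2 = {s for s in cls_then_ro2 if ro2_profile(s).passes}
        ro2_then_cls = [s for s in smiles if ro2_profile(s).passes]
        ro2_then_cls = {s for s in ro2_then_cls
                        if matches_class(s, BBClass.CARBOXYLIC_ACID)}
        assert cls_then_ro2 == ro2_then_cls


class TestClassPatterns:
    @pytest.mark.parametrize("smiles,expected", [
        ("CC(=O)CC(=O)OC(C)(C)C", True),   # beta-keto ester
        ("O=C(Cc1ccccc1)c1ccccc1", True),  # phenylbenzyl ketone
        ("CC(=O)CC#N", True),              # cyanoketone
        ("CC(=O)CS(=O)(=O)C", True),       # keto-sulfone
        ("CC(=O)CC", False),               # plain ketone: not activated
        ("CCO", False),
    ])
    def test_active_methylene(self, smiles, expected):
        assert matches_class(smiles, BBClass.ACTIVE_METHYLENE) is expected

    @pytest.mark.parametrize("smiles,expected", [
        ("C#CC", True),
        ("CC#CC", False),          # internal alkyne
        ("c1ccccc1", False),
    ])
    def test_terminal_alkyne(self, smiles, expected):
        assert matches_class(smiles, BBClass.TERMINAL_ALKYNE) is expected

    @pytest.mark.parametrize("smiles,expected", [
        ("CC(=O)O", True),
        ("OC(=O)CC#C", False),             # alkyne cross-reactivity guard
        ("OC(=O)CCN=[N+]=[N-]", False),    # azide cross-reactivity guard
        ("CC(=O)OC", False),               # ester is not an acid
    ])
    def test_carboxylic_acid(self, smiles, expected):
        assert matches_class(smiles, BBClass.CARBOXYLIC_ACID) is expected
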
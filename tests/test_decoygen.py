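import numpy as np
import pytest

from conftest import random_rigid
from ppiscreen.decoygen import (
    ChainStructure,
    build_decoy,
    build_decoy_recipes,
    make_pairing_index,
    nearest_analog,
    rank_analogs,
    select_decoy_analogs,
    size_bias_report,
    tm_d0,
    tm_score,
)
from ppiscreen.errors import AnalogError, LengthError
from ppiscreen.structio import AtomRecord, Residue
from ppiscreen.synth import make_chain, make_complex


def _transformed_chain(chain, seed, chain_id=None):
    R, t = random_rigid(seed)
    return ChainStructure(chain_id or chain.chain_id, [
        Residue(chain_id or r.chain_id, r.seq_index, r.aa_type,
                [AtomRecord(a.atom_name, a.element, R @ a.coords + t, a.temp_factor)
                 for a in r.atoms], r.icode)
        for r in chain.residues
    ])


class TestTmScore:
    def test_self_identity(self):
        for seed, ss in ((1, "H"), (2, "E"), (3, "HC")):
            c = make_chain(25, ss, seed=seed, chain_id="c")
            assert tm_score(c, c) == pytest.approx(1.0)

    def test_d0_closed_form(self):
        assert tm_d0(165) == pytest.approx(1.24 * 150 ** (1 / 3) - 1.8, abs=1e-6)
        assert tm_d0(165) == pytest.approx(4.788, abs=2e-3)

    def test_d0_floor(self):
        assert tm_d0(16) == 0.5

    def test_short_chain_rejected(self):
        short = make_chain(15, "H", seed=1)
        short14 = ChainStructure("s", short.residues[:14])
        ok = make_chain(20, "H", seed=2)
        with pytest.raises(LengthError):
            tm_score(short14, ok)

    def test_rigid_invariance(self):
        a = make_chain(30, "HC", seed=4, chain_id="a")
        b = make_chain(28, "H", seed=5, chain_id="b")
        base = tm_score(a, b)
        assert tm_score(_transformed_chain(a, 11), b) == pytest.approx(base, abs=1e-3)
        assert tm_score(a, _transformed_chain(b, 12)) == pytest.approx(base, abs=1e-3)

    def test_unrelated_folds_below_half(self):
        helix = make_chain(30, "H", seed=6, chain_id="h")
        coil = make_chain(30, "C", seed=7, chain_id="s")
        assert tm_score(coil, helix) < 0.5

    def test_normalization_asymmetry(self):
        a = make_chain(20, "H", seed=8, chain_id="a")
        b = make_chain(40, "HC", seed=9, chain_id="b")
        # fragment of a helix vs a longer mixed chain: normalizing by the
        # longer reference gives the lower score
        assert tm_score(a, b) != pytest.approx(tm_score(b, a), abs=1e-3)


def _library():
    """6 proteins: two fold families; rigid copies make analogs unambiguous."""
    h = make_chain(24, "H", seed=1, chain_id="h0")
    c = make_chain(24, "C", seed=2, chain_id="c0")
    lib = {
        "h0": h,
        "h1": _transformed_chain(h, 21, "h1"),
        "h2": _transformed_chain(h, 22, "h2"),
        "c0": c,
        "c1": _transformed_chain(c, 23, "c1"),
        "c2": _transformed_chain(c, 24, "c2"),
    }
    return lib


class TestAnalogSelection:
    def test_nearest_is_same_fold(self):
        lib = _library()
        pidx = make_pairing_index([("h0", "c0"), ("h1", "c1"), ("h2", "c2")])
        aid, tm, rank = nearest_analog("h0", lib, pidx)
        assert aid in ("h1", "h2")
        assert tm > 0.9
        assert rank == 0

    def test_excludes_self_and_partner(self):
        lib = _library()
        pidx = make_pairing_index([("h0", "c0")])
        ranked = [a for a, _ in rank_analogs("h0", lib, pidx)]
        assert "h0" not in ranked and "c0" not in ranked

    def test_tm_tie_breaks_lexicographically(self):
        h = make_chain(24, "H", seed=1, chain_id="h0")
        lib = {
            "h0": h,
            "zz": ChainStructure("zz", h.residues),  # identical geometry
            "aa": ChainStructure("aa", h.residues),  # identical geometry
        }
        aid, tm, _ = nearest_analog("h0", lib, set())
        assert aid == "aa"
        assert tm == pytest.approx(1.0)

    def test_second_best_when_best_pair_is_active(self):
        lib = _library()
        # make h1-c1 the only active pairing besides the template h0-c0;
        # best analogs for (h0, c0) are from {h1,h2} x {c1,c2}; force the
        # top combination to be active so one slot must step down
        actives = [("h0", "c0"), ("h1", "c1"), ("h2", "c2")]
        pidx = make_pairing_index(actives)
        (a1, t1, r1), (a2, t2, r2) = select_decoy_analogs("h0", "c0", lib, pidx)
        assert frozenset((a1, a2)) not in pidx
        best1 = rank_analogs("h0", lib, pidx)[0][0]
        best2 = rank_analogs("c0", lib, pidx)[0][0]
        if frozenset((best1, best2)) in pidx:
            assert (r1, r2) in ((0, 1), (1, 0))

    def test_recipes_never_reconstitute_actives(self):
        lib = _library()
        actives = [("h0", "c0"), ("h1", "c1"), ("h2", "c2")]
        complexes = [(f"cpx{i}", a, b) for i, (a, b) in enumerate(actives)]
        pidx = make_pairing_index(actives)
        recipes = build_decoy_recipes(complexes, lib, pidx)
        for r in recipes:
            assert frozenset((r.analog_id_1, r.analog_id_2)) not in pidx

    def test_recipes_match_exhaustive_search(self):
        """Greedy selection equals brute force over all admissible analog pairs."""
        lib = _library()
        actives = [("h0", "c0"), ("h1", "c1"), ("h2", "c2")]
        pidx = make_pairing_index(actives)
        for cid, id1, id2 in [("x", "h0", "c0"), ("y", "h1", "c1")]:
            (a1, t1, k1), (a2, t2, k2) = select_decoy_analogs(id1, id2, lib, pidx)
            r1 = rank_analogs(id1, lib, pidx)
            r2 = rank_analogs(id2, lib, pidx)
            # oracle: first admissible combination in (rank-sum, slot-1-rank) order
            oracle = None
            for total in range(len(r1) + len(r2)):
                for k in range(min(total + 1, len(r1))):
                    l = total - k
                    if l >= len(r2):
                        continue
                    c1, c2 = r1[k][0], r2[l][0]
                    if c1 == c2 or frozenset((c1, c2)) in pidx:
                        continue
                    oracle = (c1, c2)
                    break
                if oracle:
                    break
            assert (a1, a2) == oracle

    def test_small_library_rejected(self):
        lib = {k: v for k, v in list(_library().items())[:2]}
        with pytest.raises(AnalogError):
            rank_analogs(next(iter(lib)), lib, set())


class TestBuildDecoy:
    def test_identical_analogs_reproduce_template_geometry(self):
        lib = _library()
        template = make_complex([lib["h0"], lib["c0"]], "docked", seed=5,
                                complex_id="t0")
        decoy, seqs, recipe = build_decoy(template, lib["h0"], lib["c0"])
        for e in (1, 2):
            tmpl_idx = template.entity_indices(e)
            tres = template.residues()
            dres = decoy.residues()
            didx = decoy.entity_indices(e)
            for ti, di in zip(tmpl_idx, didx):
                assert np.allclose(tres[ti].coord("CA"), dres[di].coord("CA"), atol=1e-6)
        assert recipe.transforms[0].rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rigid_copy_analog_transform_recovered(self):
        lib = _library()
        template = make_complex([lib["h0"], lib["c0"]], "docked", seed=5,
                                complex_id="t0")
        decoy, seqs, recipe = build_decoy(template, lib["h1"], lib["c1"])
        # h1 is a rigid copy of h0: superposition must be exact
        assert recipe.transforms[0].rmsd == pytest.approx(0.0, abs=1e-6)
        assert recipe.transforms[1].rmsd == pytest.approx(0.0, abs=1e-6)
        assert [s[1] for s in seqs] == [lib["h1"].sequence(), lib["c1"].sequence()]

    def test_rank_names(self):
        from ppiscreen.decoygen import DecoyRecipe

        assert DecoyRecipe.rank_name(0) == "best"
        assert DecoyRecipe.rank_name(1) == "second_best"


class TestSizeBias:
    def _recipes(self):
        lib = _library()
        actives = [("h0", "c0"), ("h1", "c1"), ("h2", "c2")]
        complexes = [(f"cpx{i}", a, b) for i, (a, b) in enumerate(actives)]
        templates = {c[0]: (c[1], c[2]) for c in complexes}
        recipes = build_decoy_recipes(complexes, lib, make_pairing_index(actives))
        return recipes, lib, templates

    def test_equal_lengths_ratio_one(self):
        recipes, lib, templates = self._recipes()
        report = size_bias_report(recipes, lib, templates)
        assert report["mean_ratio"] == pytest.approx(1.0)

    def test_longer_analogs_ratio_above_one(self):
        lib = _library()
        big = make_chain(36, "H", seed=31, chain_id="hbig")
        lib["hbig"] = big
        from ppiscreen.decoygen import DecoyRecipe

        recipes = [DecoyRecipe("cpx0", "hbig", "c1", 0.9, 0.9, 0, 0)]
        templates = {"cpx0": ("h0", "c0")}
        report = size_bias_report(recipes, lib, templates)
        assert report["mean_ratio"] > 1.0

    def test_ratio_distribution_matches_recount(self):
        recipes, lib, templates = self._recipes()
        report = size_bias_report(recipes, lib, templates)
        expected = []
        for r in recipes:
            t1, t2 = templates[r.template_complex_id]
            expected.append(len(lib[r.analog_id_1]) / len(lib[t1]))
            expected.append(len(lib[r.analog_id_2]) / len(lib[t2]))
        assert np.allclose(sorted(report["ratios"]), sorted(expected))
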
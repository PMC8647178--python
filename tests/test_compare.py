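"""Structure completeness: Cα matching against a deposited reference."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from buildrank.compare import (
    EmptyModelError,
    Residue,
    StructureModel,
    read_model,
    structure_completeness,
    write_model,
)
from buildrank.synthetic import make_model_pair


def chain(positions, types, chain_id="A"):
    return StructureModel(
        residues=[
            Residue(chain_id, i + 1, "", t, tuple(p))
            for i, (p, t) in enumerate(zip(positions, types))
        ]
    )


def random_protein_instance(seed):
    """Random built/deposited pair with protein-like geometry.

    Deposited residues sit 3.8 Å apart on a jittered path; built residues
    are displaced copies (some duplicated, exercising one-to-one matching),
    wrong-type copies, or out-of-cutoff decoys.
    """
    from buildrank.synthetic import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 13))
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * 3.8
    pos[:, 1] = rng.uniform(-0.3, 0.3, n)
    pos[:, 2] = rng.uniform(-0.3, 0.3, n)
    types = rng.choice(AMINO_ACIDS[:6], n)  # few types -> eligible collisions
    deposited = StructureModel(
        residues=[Residue("A", i + 1, "", types[i], tuple(pos[i])) for i in range(n)]
    )
    built = []

    def displaced(i, lo, hi):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        return tuple(pos[i] + rng.uniform(lo, hi) * d)

    k = 0
    for i in range(n):
        r = rng.random()
        if r < 0.5:  # reproduced within cutoff
            k += 1
            built.append(Residue("B", k, "", types[i], displaced(i, 0.0, 0.95)))
            if rng.random() < 0.2:  # duplicate copy
                k += 1
                built.append(Residue("B", k, "", types[i], displaced(i, 0.0, 0.95)))
        elif r < 0.65:  # right place, wrong type
            mutated = rng.choice([a for a in AMINO_ACIDS[:6] if a != types[i]])
            k += 1
            built.append(Residue("B", k, "", mutated, tuple(pos[i])))
        elif r < 0.8:  # decoy outside the cutoff
            k += 1
            built.append(Residue("B", k, "", types[i], displaced(i, 1.05, 3.0)))
    return StructureModel(residues=built), deposited


def optimal_match_count(built, deposited, cutoff=1.0):
    """Maximum bipartite matching on the eligibility graph (oracle)."""
    bi, bxyz = built.ca_array()
    di, dxyz = deposited.ca_array()
    if len(bi) == 0 or len(di) == 0:
        return 0
    dist = np.linalg.norm(bxyz[:, None] - dxyz[None, :], axis=2)
    btypes = np.array([built.residues[i].residue_type for i in bi])
    dtypes = np.array([deposited.residues[i].residue_type for i in di])
    eligible = (dist < cutoff) & (btypes[:, None] == dtypes[None, :])
    if not eligible.any():
        return 0
    matching = maximum_bipartite_matching(csr_matrix(eligible), perm_type="column")
    return int((matching >= 0).sum())


class TestCompleteness:
    def test_identity_model_is_complete(self):
        pair = make_model_pair(15, 1.0, displacement=0.0, seed=0)
        result = structure_completeness(pair.deposited, pair.deposited)
        assert result.completeness == 1.0
        assert result.n_matched == result.n_deposited == 15

    def test_empty_built_model(self):
        pair = make_model_pair(10, 1.0, seed=1)
        result = structure_completeness(StructureModel(residues=[]), pair.deposited)
        assert result.completeness == 0.0

    def test_deposited_without_ca_raises(self):
        deposited = StructureModel(residues=[Residue("A", 1, "", "ALA", None)])
        with pytest.raises(EmptyModelError):
            structure_completeness(StructureModel(residues=[]), deposited)

    def test_hand_constructed_mixture(self):
        """6/10 same type within cutoff, 1 wrong type, 1 too far -> 0.6."""
        rng = np.random.default_rng(0)
        positions = np.column_stack([np.arange(10) * 5.0, np.zeros(10), np.zeros(10)])
        types = ["ALA", "GLY", "SER", "THR", "VAL", "LEU", "ILE", "PRO", "MET", "PHE"]
        deposited = chain(positions, types)
        built_pos, built_types = [], []
        for i in range(6):  # reproduced, displaced 0.3 Å
            offset = rng.normal(size=3)
            offset *= 0.3 / np.linalg.norm(offset)
            built_pos.append(positions[i] + offset)
            built_types.append(types[i])
        built_pos.append(positions[6])  # right place, wrong type
        built_types.append("TRP")
        built_pos.append(positions[7] + np.array([1.2, 0.0, 0.0]))  # too far
        built_types.append(types[7])
        result = structure_completeness(chain(built_pos, built_types), deposited)
        assert result.completeness == pytest.approx(0.6)
        assert result.n_matched == 6
        assert result.n_matched == optimal_match_count(chain(built_pos, built_types), deposited)

    def test_strict_cutoff_inequality(self):
        deposited = chain([[0.0, 0.0, 0.0]], ["ALA"])
        exactly_at = chain([[1.0, 0.0, 0.0]], ["ALA"])
        just_inside = chain([[0.999, 0.0, 0.0]], ["ALA"])
        assert structure_completeness(exactly_at, deposited).completeness == 0.0
        assert structure_completeness(just_inside, deposited).completeness == 1.0

    def test_monotone_in_cutoff(self):
        pair = make_model_pair(30, 0.8, displacement=0.6, seed=3)
        values = [
            structure_completeness(pair.built, pair.deposited, cutoff=c).completeness
            for c in (0.25, 0.5, 0.75, 1.0, 2.0)
        ]
        assert values == sorted(values)

    def test_far_translation_destroys_matches(self):
        pair = make_model_pair(12, 1.0, displacement=0.0, seed=4)
        moved = StructureModel(
            residues=[
                Residue(r.chain_id, r.seq_num, r.insertion_code, r.residue_type,
                        (r.ca_position[0] + 100.0, r.ca_position[1], r.ca_position[2]))
                for r in pair.built.residues
            ]
        )
        assert structure_completeness(moved, pair.deposited).completeness == 0.0

    def test_matching_is_one_to_one(self):
        # two built copies of one deposited residue: only one may match
        deposited = chain([[0.0, 0.0, 0.0]], ["GLY"])
        built = chain([[0.2, 0.0, 0.0], [0.0, 0.3, 0.0]], ["GLY", "GLY"], chain_id="B")
        result = structure_completeness(built, deposited)
        assert result.n_matched == 1
        built_ids = [b for b, _, _ in result.matched_pairs]
        assert len(built_ids) == len(set(built_ids))

    @pytest.mark.parametrize("seed", range(40))
    def test_greedy_count_equals_optimal_bipartite(self, seed):
        """Greedy distance-ordered matching recovers the optimal match count
        on random protein-like instances of <= 12 residues (spaced deposited
        backbone; built residues displaced, mutated, duplicated or decoyed)."""
        built, deposited = random_protein_instance(seed)
        result = structure_completeness(built, deposited)
        assert result.n_matched == optimal_match_count(built, deposited)


class TestModelIO:
    def test_round_trip_pdb(self, tmp_path):
        pair = make_model_pair(5, 0.8, seed=5)
        path = tmp_path / "model.pdb"
        write_model(pair.deposited, path)
        back = read_model(path)
        assert len(back) == 5
        for orig, new in zip(pair.deposited.residues, back.residues):
            assert (orig.chain_id, orig.seq_num, orig.residue_type) == (
                new.chain_id, new.seq_num, new.residue_type)
            assert new.ca_position == pytest.approx(orig.ca_position, abs=1e-3)

    def test_pdb_and_mmcif_renderings_agree(self, tmp_path):
        pair = make_model_pair(7, 1.0, seed=6)
        pdb_path, cif_path = tmp_path / "m.pdb", tmp_path / "m.cif"
        write_model(pair.deposited, pdb_path)
        write_model(pair.deposited, cif_path)
        from_pdb, from_cif = read_model(pdb_path), read_model(cif_path)
        assert len(from_pdb) == len(from_cif)
        for a, b in zip(from_pdb.residues, from_cif.residues):
            assert (a.chain_id, a.seq_num, a.residue_type) == (b.chain_id, b.seq_num, b.residue_type)
            assert a.ca_position == pytest.approx(b.ca_position, abs=1e-3)

    def test_residue_without_ca_preserved(self, tmp_path):
        residues = [Residue("A", i + 1, "", "ALA", (i * 4.0, 0.0, 0.0)) for i in range(4)]
        residues.append(Residue("A", 5, "", "GLY", None))
        path = tmp_path / "gap.pdb"
        write_model(StructureModel(residues=residues), path)
        back = read_model(path)
        assert len(back) == 5
        assert sum(r.ca_position is not None for r in back.residues) == 4

    def test_completeness_result_serializes(self):
        pair = make_model_pair(8, 0.5, seed=7)
        result = structure_completeness(pair.built, pair.deposited)
        import json
        payload = json.loads(result.to_json())
        assert payload["n_matched"] == result.n_matched
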
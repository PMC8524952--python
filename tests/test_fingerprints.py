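"""MAP4 fingerprinting: shingle enumeration, MinHash Jaccard estimation,
similarity, and the comparator encodings."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, DataStructs

from nporigin.errors import DegenerateInputError, DimensionError
from nporigin.fingerprints import (
    MAP4Fingerprint,
    comparator_fingerprint,
    enumerate_shingles,
    map4_fingerprint,
    map4_similarity,
    minhash,
    property_vector,
)


def _brute_force_shingles(smiles, radii=(1, 2)):
    """Independent enumeration: shortest paths via explicit BFS over the
    bond graph, environments via RDKit path extraction."""
    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    adj = {i: [] for i in range(n)}
    for b in mol.GetBonds():
        adj[b.GetBeginAtomIdx()].append(b.GetEndAtomIdx())
        adj[b.GetEndAtomIdx()].append(b.GetBeginAtomIdx())

    def bfs(src):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    def env(i, r):
        bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, r, i)
        if not bonds:
            return Chem.MolFragmentToSmiles(mol, [i], rootedAtAtom=i,
                                            isomericSmiles=False)
        atoms = {i}
        for bid in bonds:
            bond = mol.GetBondWithIdx(bid)
            atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        return Chem.MolFragmentToSmiles(mol, sorted(atoms), bondsToUse=list(bonds),
                                        rootedAtAtom=i, isomericSmiles=False)

    out = set()
    for i in range(n):
        dist = bfs(i)
        for j in range(i + 1, n):
            if j not in dist:
                continue
            for r in radii:
                a, b = sorted((env(i, r), env(j, r)))
                out.add(f"{a}|{dist[j]}|{b}")
    return out


class TestShingles:
    @pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1O", "NCC(=O)NCC(=O)O"])
    def test_matches_brute_force_enumeration(self, smiles):
        assert enumerate_shingles(smiles) == _brute_force_shingles(smiles)

    def test_single_heavy_atom_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            enumerate_shingles("C")  # methane: no atom pair exists

    def test_equivalent_smiles_give_identical_shingles(self):
        assert enumerate_shingles("OCC") == enumerate_shingles("CCO")

    def test_shingle_format(self):
        for s in enumerate_shingles("CCO"):
            a, d, b = s.split("|")
            assert int(d) >= 1
            assert a <= b  # lexicographic ordering of the two environments

    def test_disconnected_fragments_skip_cross_pairs(self):
        # sodium acetate: no path between the ion and the acetate fragment,
        # so the single-atom counterion appears in no shingle at all
        shingles = enumerate_shingles("CC(=O)[O-].[Na+]")
        assert shingles == enumerate_shingles("CC(=O)[O-]")


class TestMinHash:
    def test_identical_sets_identical_fingerprints(self):
        s = enumerate_shingles("c1ccccc1O")
        a, b = minhash(s, d=256), minhash(s, d=256)
        assert np.array_equal(a.values, b.values)

    def test_empty_set_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            minhash(set(), d=64)

    def test_disjoint_sets_collide_rarely(self):
        a = {f"left-{i}" for i in range(50)}
        b = {f"right-{i}" for i in range(50)}
        frac = map4_similarity(minhash(a, d=1024), minhash(b, d=1024))
        assert frac <= 3 * np.sqrt(0.25 / 1024)

    def test_match_fraction_estimates_constructed_jaccard(self):
        """|A∩B| = 10, |A∪B| = 30 gives exact Jaccard 1/3; the MinHash
        match fraction must fall within the 3-sigma binomial band."""
        shared = {f"shared-{i}" for i in range(10)}
        a = shared | {f"a-{i}" for i in range(10)}
        b = shared | {f"b-{i}" for i in range(10)}
        j = len(a & b) / len(a | b)
        assert j == pytest.approx(1 / 3)
        frac = map4_similarity(minhash(a, d=1024), minhash(b, d=1024))
        assert abs(frac - j) <= 3 * np.sqrt(j * (1 - j) / 1024)

    def test_mean_error_vs_exact_jaccard_over_molecule_pairs(self, small_dataset):
        """MinHash consistency across >= 100 random molecule pairs."""
        rng = np.random.default_rng(0)
        smiles = [m.smiles for m in small_dataset]
        shingle_sets = {s: enumerate_shingles(s) for s in set(smiles)}
        fps = {s: minhash(sh, d=1024) for s, sh in shingle_sets.items()}
        errors = []
        for _ in range(120):
            s1, s2 = rng.choice(smiles, size=2, replace=False)
            exact = len(shingle_sets[s1] & shingle_sets[s2]) / len(
                shingle_sets[s1] | shingle_sets[s2]
            )
            errors.append(abs(map4_similarity(fps[s1], fps[s2]) - exact))
        assert np.mean(errors) <= 3 * np.sqrt(0.25 / 1024)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        fp = map4_fingerprint("c1ccccc1O")
        assert map4_similarity(fp, fp) == 1.0

    def test_worked_toy_example(self):
        a = MAP4Fingerprint(values=np.array([1, 2, 3, 4], dtype=np.uint32), d=4)
        b = MAP4Fingerprint(values=np.array([1, 2, 9, 9], dtype=np.uint32), d=4)
        assert map4_similarity(a, b) == 0.5

    def test_all_different_gives_zero(self):
        a = MAP4Fingerprint(values=np.arange(8, dtype=np.uint32), d=8)
        b = MAP4Fingerprint(values=np.arange(8, 16, dtype=np.uint32), d=8)
        assert map4_similarity(a, b) == 0.0

    def test_dimension_mismatch_raises(self):
        a = MAP4Fingerprint(values=np.arange(8, dtype=np.uint32), d=8)
        b = MAP4Fingerprint(values=np.arange(4, dtype=np.uint32), d=4)
        with pytest.raises(DimensionError):
            map4_similarity(a, b)

    def test_symmetry_and_bounds(self, small_dataset):
        rng = np.random.default_rng(1)
        smiles = [m.smiles for m in small_dataset]
        for _ in range(20):
            s1, s2 = rng.choice(smiles, size=2, replace=False)
            f1, f2 = map4_fingerprint(s1, d=256), map4_fingerprint(s2, d=256)
            s12, s21 = map4_similarity(f1, f2), map4_similarity(f2, f1)
            assert s12 == s21
            assert 0.0 <= s12 <= 1.0


class TestInvariance:
    @pytest.mark.parametrize(
        "smiles", ["CC(=O)Oc1ccccc1C(=O)O", "NCC(=O)NCC(=O)O", "Oc1ccc2ccc(=O)oc2c1"]
    )
    def test_atom_order_invariance(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        n = mol.GetNumAtoms()
        rng = np.random.default_rng(7)
        base = map4_fingerprint(smiles)
        for _ in range(3):
            perm = rng.permutation(n).tolist()
            renumbered = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm))
            other = map4_fingerprint(renumbered)
            assert np.array_equal(base.values, other.values)


class TestComparators:
    def test_deterministic(self):
        a = comparator_fingerprint("CC(=O)Oc1ccccc1C(=O)O", "circular")
        b = comparator_fingerprint("CC(=O)Oc1ccccc1C(=O)O", "circular")
        assert np.array_equal(a.bits, b.bits)

    @pytest.mark.parametrize("kind", ["circular", "atom_pair"])
    def test_bit_length_and_self_tanimoto(self, kind):
        fp = comparator_fingerprint("Oc1ccc2ccc(=O)oc2c1", kind)
        assert len(fp.bits) == 1024
        x = fp.bits.astype(float)
        assert x.sum() > 0
        assert x @ x / (2 * x.sum() - x @ x) == 1.0

    def test_tanimoto_matches_rdkit_reference(self):
        """Cross-check our bit-vector Tanimoto against RDKit's own
        similarity implementation on the same folded fingerprints."""
        from nporigin.classifier import KernelSpec, compute_kernel_matrix

        pairs = [("c1ccccc1", "C1CCCCC1"), ("CCO", "CCN"),
                 ("Oc1ccc2ccc(=O)oc2c1", "c1ccccc1")]
        for s1, s2 in pairs:
            b1 = comparator_fingerprint(s1, "circular").bits
            b2 = comparator_fingerprint(s2, "circular").bits
            mine = compute_kernel_matrix(
                b1[None, :], b2[None, :], KernelSpec("tanimoto")
            )[0, 0]
            v1 = AllChem.GetMorganFingerprintAsBitVect(Chem.MolFromSmiles(s1), 2, 1024)
            v2 = AllChem.GetMorganFingerprintAsBitVect(Chem.MolFromSmiles(s2), 2, 1024)
            ref = DataStructs.TanimotoSimilarity(v1, v2)
            assert mine == pytest.approx(ref, abs=1e-12)


class TestPropertyVector:
    def test_dihydropyridine_molecular_weight_entry(self):
        v = property_vector("C1C=CC=CN1")
        assert v[0] == pytest.approx(81, abs=0.5)

    def test_benzene_entries(self):
        v = property_vector("c1ccccc1")
        assert v[1] == 0.0        # Fsp3
        assert v[5] == 6          # carbons
        assert v[7] == 0          # nitrogens

    def test_ethanol_counts(self):
        v = property_vector("CCO")
        assert (v[8], v[9], v[6]) == (3, 2, 1)

    def test_has_exactly_eleven_entries(self):
        assert property_vector("CCO").shape == (11,)
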
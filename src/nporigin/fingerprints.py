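"""MinHashed atom-pair (MAP4) fingerprints and comparator encodings.

The MAP4 fingerprint describes a molecule as the set of *shingles*
``"<smilesA>|<distance>|<smilesB>"``: for every unordered pair of heavy
atoms, the canonical SMILES of the circular substructures of radius 1 and 2
around each atom, joined with the topological (shortest-path, in bonds)
distance between the two atoms. The shingle set is then MinHashed to a
fixed-length vector of ``d`` unsigned integers, so that the fraction of
positions at which two fingerprints agree is an unbiased estimate of the
Jaccard similarity of the underlying shingle sets.

Comparator encodings used by the baseline classifiers are also provided:
the folded circular substructure fingerprint of radius 2 (1024 bits), the
folded topological atom-pair fingerprint (1024 bits), and an
11-descriptor physico-chemical property vector.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator, rdMolDescriptors

from .chem import parse_smiles, strip_stereo
from .errors import DegenerateInputError, DimensionError

DEFAULT_DIMENSIONS = 1024
DEFAULT_RADII = (1, 2)
DEFAULT_HASH_SEED = 42

# Mersenne prime modulus of the universal hash family. Keeping p < 2^31
# means a_k * x stays inside uint64 and the whole MinHash sweep vectorizes.
_MERSENNE_P = np.uint64(2**31 - 1)

#: Fixed order of the 11 physico-chemical descriptors.
PROPERTY_NAMES: tuple[str, ...] = (
    "mw", "fsp3", "hbd", "hba", "alogp",
    "n_carbon", "n_oxygen", "n_nitrogen", "n_atoms", "n_bonds", "tpsa",
)


@dataclass(frozen=True)
class MAP4Fingerprint:
    """MinHash vector of a molecule's shingle set."""

    values: np.ndarray  # shape (d,), unsigned integers
    d: int = DEFAULT_DIMENSIONS

    def __post_init__(self):
        if len(self.values) != self.d:
            raise DimensionError(f"expected {self.d} values, got {len(self.values)}")


@dataclass(frozen=True)
class ComparatorFingerprint:
    """Folded binary fingerprint (circular or atom-pair), 1024 bits."""

    bits: np.ndarray
    kind: str = "circular"  # "circular" | "atom_pair"

    def __post_init__(self):
        if len(self.bits) != DEFAULT_DIMENSIONS:
            raise DimensionError(f"expected {DEFAULT_DIMENSIONS} bits, got {len(self.bits)}")


# ---------------------------------------------------------------------------
# Shingles
# ---------------------------------------------------------------------------

def _atom_environment_smiles(mol: Chem.Mol, atom_idx: int, radius: int) -> str:
    """Canonical SMILES of the radius-``radius`` circular environment,
    rooted at the central atom, without stereo markers."""
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
    if not bond_ids:
        # isolated atom (single-atom fragment): environment is the atom itself
        return Chem.MolFragmentToSmiles(
            mol, atomsToUse=[atom_idx], rootedAtAtom=atom_idx, isomericSmiles=False
        )
    atoms = {atom_idx}
    for bid in bond_ids:
        bond = mol.GetBondWithIdx(bid)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=sorted(atoms),
        bondsToUse=list(bond_ids),
        rootedAtAtom=atom_idx,
        canonical=True,
        isomericSmiles=False,
    )


def enumerate_shingles(
    smiles_or_mol,
    radii: tuple[int, ...] = DEFAULT_RADII,
    record_id: str | None = None,
) -> frozenset[str]:
    """All atom-pair shingles of a molecule.

    For every unordered pair of distinct heavy atoms (i, j) connected by a
    bond path and every radius r, emits
    ``min(env, env') | distance | max(env, env')`` where the environments
    are canonical rooted substructure SMILES. Atom pairs in different
    disconnected fragments have no topological distance and are skipped.

    Raises :class:`DegenerateInputError` for molecules with < 2 heavy atoms.
    """
    mol = smiles_or_mol if isinstance(smiles_or_mol, Chem.Mol) else parse_smiles(
        smiles_or_mol, record_id
    )
    n = mol.GetNumAtoms()
    if n < 2:
        raise DegenerateInputError(
            f"MAP4 needs >= 2 heavy atoms, got {n}"
            + (f" (record {record_id})" if record_id else "")
        )
    dist = Chem.GetDistanceMatrix(mol)
    envs = {
        r: [_atom_environment_smiles(mol, i, r) for i in range(n)] for r in radii
    }
    shingles = set()
    for i in range(n):
        for j in range(i + 1, n):
            d_ij = dist[i, j]
            if not np.isfinite(d_ij) or d_ij > n:  # disconnected fragments
                continue
            d_str = str(int(d_ij))
            for r in radii:
                a, b = sorted((envs[r][i], envs[r][j]))
                shingles.add(f"{a}|{d_str}|{b}")
    if not shingles:
        raise DegenerateInputError("no connected atom pair found")
    return frozenset(shingles)


# ---------------------------------------------------------------------------
# MinHash
# ---------------------------------------------------------------------------

def _hash_coefficients(d: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    p = int(_MERSENNE_P)
    a = rng.integers(1, p, size=d, dtype=np.uint64)
    b = rng.integers(0, p, size=d, dtype=np.uint64)
    return a, b


_COEFF_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _coefficients(d: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    key = (d, seed)
    if key not in _COEFF_CACHE:
        _COEFF_CACHE[key] = _hash_coefficients(d, seed)
    return _COEFF_CACHE[key]


def _string_hashes(shingles) -> np.ndarray:
    """Stable 32-bit hash (CRC-32) of each shingle string, reduced mod p."""
    out = np.fromiter(
        (zlib.crc32(s.encode("utf-8")) for s in shingles),
        dtype=np.uint64,
        count=len(shingles),
    )
    return out % _MERSENNE_P


def minhash(
    shingles,
    d: int = DEFAULT_DIMENSIONS,
    seed: int = DEFAULT_HASH_SEED,
) -> MAP4Fingerprint:
    """MinHash a shingle set to a ``d``-dimensional fingerprint.

    Uses ``d`` universal hash functions h_k(x) = (a_k x + b_k) mod p with
    p = 2^31 - 1; position k of the fingerprint is the minimum of h_k over
    the (pre-hashed) shingle strings. Deterministic for a given
    (shingles, d, seed).
    """
    if d < 1:
        raise DimensionError(f"d must be >= 1, got {d}")
    shingles = sorted(shingles) if not isinstance(shingles, (list, tuple)) else shingles
    if len(shingles) == 0:
        raise DegenerateInputError("cannot MinHash an empty shingle set")
    a, b = _coefficients(d, seed)
    x = _string_hashes(shingles)  # (n,)
    # (d, n) sweep; chunk the hash axis to bound the temporary at ~32 MB
    n = len(x)
    values = np.empty(d, dtype=np.uint64)
    chunk = max(1, (4 << 20) // max(n, 1))
    for start in range(0, d, chunk):
        stop = min(start + chunk, d)
        h = (a[start:stop, None] * x[None, :] + b[start:stop, None]) % _MERSENNE_P
        values[start:stop] = h.min(axis=1)
    return MAP4Fingerprint(values=values.astype(np.uint32), d=d)


def map4_fingerprint(
    smiles: str,
    d: int = DEFAULT_DIMENSIONS,
    radii: tuple[int, ...] = DEFAULT_RADII,
    seed: int = DEFAULT_HASH_SEED,
    record_id: str | None = None,
) -> MAP4Fingerprint:
    """Shingle a molecule and MinHash the result (the MAP4 fingerprint)."""
    return minhash(enumerate_shingles(smiles, radii, record_id), d=d, seed=seed)


def map4_similarity(a, b) -> float:
    """Fraction of positions at which two MinHash vectors agree.

    This is the paper's kernel: count the indices where the two
    fingerprints hold the same value and divide by the fingerprint length.
    It estimates the Jaccard similarity of the two shingle sets.
    """
    va = a.values if isinstance(a, MAP4Fingerprint) else np.asarray(a)
    vb = b.values if isinstance(b, MAP4Fingerprint) else np.asarray(b)
    if len(va) != len(vb):
        raise DimensionError(f"dimension mismatch: {len(va)} vs {len(vb)}")
    return float(np.mean(va == vb))


def fingerprint_matrix(
    smiles_list,
    d: int = DEFAULT_DIMENSIONS,
    radii: tuple[int, ...] = DEFAULT_RADII,
    seed: int = DEFAULT_HASH_SEED,
) -> np.ndarray:
    """Stack MAP4 fingerprints of many molecules into an (n, d) array."""
    return np.stack(
        [map4_fingerprint(s, d=d, radii=radii, seed=seed).values for s in smiles_list]
    )


# ---------------------------------------------------------------------------
# Comparator encodings
# ---------------------------------------------------------------------------

_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=2, fpSize=DEFAULT_DIMENSIONS
)
_AP_GEN = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=DEFAULT_DIMENSIONS)


def comparator_fingerprint(
    smiles: str, kind: str = "circular", record_id: str | None = None
) -> ComparatorFingerprint:
    """Folded 1024-bit circular (radius 2) or topological atom-pair fingerprint."""
    mol = parse_smiles(smiles, record_id)
    if kind == "circular":
        bits = _MORGAN_GEN.GetFingerprintAsNumPy(mol)
    elif kind == "atom_pair":
        bits = _AP_GEN.GetFingerprintAsNumPy(mol)
    else:
        raise ValueError(f"unknown comparator kind: {kind!r}")
    return ComparatorFingerprint(bits=bits.astype(np.uint8), kind=kind)


def comparator_matrix(smiles_list, kind: str = "circular") -> np.ndarray:
    return np.stack([comparator_fingerprint(s, kind).bits for s in smiles_list])


def property_vector(smiles: str, record_id: str | None = None) -> np.ndarray:
    """The 11 physico-chemical descriptors in the fixed order
    (MW, Fsp3, HBD, HBA, AlogP, #C, #O, #N, #atoms, #bonds, TPSA).

    Values are raw; standardization to zero mean / unit variance is the
    classifier's job, fitted on training data only.
    """
    mol = parse_smiles(smiles, record_id)
    atoms = mol.GetAtoms()
    return np.array(
        [
            Descriptors.MolWt(mol),
            rdMolDescriptors.CalcFractionCSP3(mol),
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            Crippen.MolLogP(mol),
            sum(1 for a in atoms if a.GetAtomicNum() == 6),
            sum(1 for a in atoms if a.GetAtomicNum() == 8),
            sum(1 for a in atoms if a.GetAtomicNum() == 7),
            mol.GetNumAtoms(),
            mol.GetNumBonds(),
            rdMolDescriptors.CalcTPSA(mol),
        ],
        dtype=float,
    )


def property_matrix(smiles_list) -> np.ndarray:
    return np.stack([property_vector(s) for s in smiles_list])


def featurize(
    smiles_list,
    representation: str,
    d: int = DEFAULT_DIMENSIONS,
    radii: tuple[int, ...] = DEFAULT_RADII,
    seed: int = DEFAULT_HASH_SEED,
    strip_stereochemistry: bool = False,
) -> np.ndarray:
    """Encode molecules for a given representation.

    representation: "map4" | "circular" | "atom_pair" | "properties".
    """
    if strip_stereochemistry:
        smiles_list = [
            Chem.MolToSmiles(strip_stereo(parse_smiles(s))) for s in smiles_list
        ]
    if representation == "map4":
        return fingerprint_matrix(smiles_list, d=d, radii=radii, seed=seed)
    if representation in ("circular", "atom_pair"):
        return comparator_matrix(smiles_list, kind=representation)
    if representation == "properties":
        return property_matrix(smiles_list)
    raise ValueError(f"unknown representation: {representation!r}")
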
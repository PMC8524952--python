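"""Seed-reproducible synthetic natural-product-like molecules.

Real NP collections show a strong association between biological origin and
structural class: plant NPs are rich in (often glycosylated) polyphenols
and terpenoids of intermediate molecular weight, bacterial NPs are rich in
linear and cyclic peptides reaching high molecular weight, and fungal NPs
are dominated by small, moderately lipophilic polyketides. This module
generates labeled molecules with exactly that categorical structure so the
whole pipeline — curation, fingerprinting, classification, layout — can be
exercised end to end without any external database.

Everything is assembled from small fixed scaffold libraries embedded in the
code: bacterial-like molecules are peptides condensed from the 20
proteinogenic amino-acid fragments, plant-like molecules are decorated
polyphenol/terpenoid cores with probabilistic O-glycosylation, fungal-like
molecules are small aromatic/polyketide scaffolds. Default mixture
parameters follow the published per-class composition of the curated NP
collection this emulates (24% of plant entries glycosylated, 31% of fungal
entries at MW <= 200, peptide lengths 3-12 residues).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdmolops

from .errors import ConfigurationError

ORIGINS: tuple[str, ...] = ("plant", "fungi", "bacteria")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic dataset generator.

    The defaults are the study conditions: class-balanced sampling,
    plant-class glycosylation at 24%, fungal small-molecule fraction 31%,
    bacterial peptides of 3-12 residues.
    """

    n_per_class: int = 200
    seed: int = 7
    peptide_length_range: tuple[int, int] = (3, 12)
    glycosylation_prob_plant: float = 0.24
    glycosylation_prob_other: float = 0.05
    small_mol_fraction_fungal: float = 0.31
    cyclic_peptide_prob: float = 0.4

    def __post_init__(self):
        for name in ("glycosylation_prob_plant", "glycosylation_prob_other",
                     "small_mol_fraction_fungal", "cyclic_peptide_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.n_per_class < 1:
            raise ConfigurationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        lo, hi = self.peptide_length_range
        if lo < 2 or hi < lo:
            raise ConfigurationError(
                f"peptide_length_range must satisfy 2 <= min <= max, got {self.peptide_length_range}"
            )


@dataclass(frozen=True)
class LabeledMolecule:
    smiles: str
    origin: str


# ---------------------------------------------------------------------------
# Scaffold libraries (fixed, embedded; >= 10 per class)
# ---------------------------------------------------------------------------

# Plant-like cores: polyphenols (flavonoids, coumarins, stilbenes, lignans)
# and hydroxylated terpenoids; every core carries at least one OH for
# O-glycosylation.
PLANT_SCAFFOLDS: tuple[str, ...] = (
    "Oc1cc(O)c2c(=O)cc(-c3ccc(O)cc3)oc2c1",            # flavone
    "Oc1ccc(C2CC(=O)c3c(O)cc(O)cc3O2)cc1",             # flavanone
    "Oc1cc(O)c2c(=O)c(O)c(-c3ccc(O)c(O)c3)oc2c1",      # flavonol
    "OC1Cc2c(O)cc(O)cc2OC1c1ccc(O)c(O)c1",             # flavan-3-ol
    "Oc1ccc2ccc(=O)oc2c1",                             # coumarin
    "Cc1cc(=O)c2c(O)cccc2o1",                          # chromone
    "Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1",                    # stilbene
    "Oc1ccc(C(=O)C=Cc2ccc(O)cc2)cc1",                  # chalcone
    "OC(=O)C=Cc1ccc(O)c(O)c1",                         # hydroxycinnamic acid
    "COc1cc(CC(C)C(C)Cc2ccc(O)c(OC)c2)ccc1O",          # lignan
    "CC1CCC(C(C)C)C(O)C1",                             # menthane monoterpenoid
    "CC(C)=CCCC(C)(O)C=C",                             # acyclic monoterpenoid
    "CC1(C)CCC2(C(O)=O)CCC3(C)C(=CC2C1O)C1CC(C)(C)CCC1(C)CC3O",  # triterpenoid
)

# Fungal-like small scaffolds (MW <= 200, moderately lipophilic).
FUNGAL_SMALL_SCAFFOLDS: tuple[str, ...] = (
    "Cc1cccc(O)c1C(O)=O",       # 6-methylsalicylic acid type
    "Cc1cc(O)cc(O)c1C(O)=O",    # orsellinic acid type
    "CC1Cc2cccc(O)c2C(=O)O1",   # dihydroisocoumarin
    "CC1=CC(=O)OC1",            # butenolide
    "CC1=CC(=O)C=C(O)O1",       # pyranone
    "OCc1cc(O)ccc1O",           # hydroxybenzyl alcohol
    "Cc1cc(O)cc(O)c1",          # orcinol
    "O=C1OCc2ccccc21",          # benzofuranone
    "O=c1c2ccccc2oc2ccccc12",   # xanthone
    "CCC1CCC(=O)C1O",           # cyclopentanone polyketide
    "CC1CC(O)CC(=O)O1",         # delta-lactone polyketide
)

# Fungal-like mid-size polyketide scaffolds (200 < MW < 800 after assembly).
FUNGAL_MID_SCAFFOLDS: tuple[str, ...] = (
    "COC1=CC(=O)CC(C)C12Oc1c(Cl)c(OC)cc(OC)c1C2=O",    # spiro-benzofuranone
    "CC1CCC2(C)C(O)CC(C)CC2C1=O",                      # decalin polyketide
    "CC(O)CC(=O)CC(C)CC(=O)c1cc(O)cc(O)c1",            # aromatic polyketide
    "CC1OC(=O)C=C1Cc1ccc(O)cc1O",                      # butenolide-phenol
    "COc1cc2c(=O)cc(C)oc2c(Cl)c1O",                    # chlorinated chromone
    "CC1CC(C)C(=O)C(C(O)CC(C)O)C1O",                   # reduced polyketide
)

# Proteinogenic side chains as SMILES branch fragments; glycine and proline
# are handled structurally in _residue. Ring-closure digits 3/4 are reserved
# for side-chain rings, 1 for peptide macrocycles, 2 for the proline ring.
AMINO_ACID_SIDE_CHAINS: dict[str, str] = {
    "A": "C", "R": "CCCNC(=N)N", "N": "CC(N)=O", "D": "CC(O)=O",
    "C": "CS", "Q": "CCC(N)=O", "E": "CCC(O)=O", "H": "Cc3cnc[nH]3",
    "I": "C(C)CC", "L": "CC(C)C", "K": "CCCCN", "M": "CCSC",
    "F": "Cc3ccccc3", "S": "CO", "T": "C(C)O", "W": "Cc3c[nH]c4ccccc34",
    "Y": "Cc3ccc(O)cc3", "V": "C(C)C",
}
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AMINO_ACID_SIDE_CHAINS) + ["G", "P"])

_SUGAR_FRAGMENT = "C1OC(CO)C(O)C(O)C1O"  # pyranose, anomeric carbon first
_AROMATIC_SUBSTITUENTS: tuple[str, ...] = ("C", "OC", "O", "CC=C(C)C")


def _residue(code: str, first: bool, last: bool, cyclic: bool) -> str:
    """SMILES fragment of one amide-condensed residue."""
    n = "N1" if (first and cyclic) else "N"
    if code == "G":
        mid = n + "C"
    elif code == "P":
        mid = ("N12" if (first and cyclic) else "N2") + "CCCC2"
    else:
        mid = n + f"C({AMINO_ACID_SIDE_CHAINS[code]})"
    if last and cyclic:
        return mid + "C1=O"
    return mid + "C(=O)"


def assemble_peptide(sequence, cyclic: bool = False) -> str:
    """SMILES of a linear (free acid) or head-to-tail cyclic peptide."""
    parts = [
        _residue(code, first=(i == 0), last=(i == len(sequence) - 1), cyclic=cyclic)
        for i, code in enumerate(sequence)
    ]
    smiles = "".join(parts)
    return smiles if cyclic else smiles + "O"


# ---------------------------------------------------------------------------
# Molecule surgery
# ---------------------------------------------------------------------------

def _free_hydroxyl_oxygens(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 8 and a.GetTotalNumHs() >= 1 and a.GetDegree() == 1
    ]


def _glycosylate(mol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol:
    """Attach a pyranose through a randomly chosen hydroxyl oxygen.

    The new anomeric carbon ends up in a ring, bonded to the ring oxygen and
    to the (now exocyclic) glycosidic oxygen — guaranteeing a match of the
    glycoside SMARTS used in curation. Returns ``mol`` unchanged when no
    free hydroxyl exists.
    """
    hydroxyls = _free_hydroxyl_oxygens(mol)
    if not hydroxyls:
        return mol
    o_idx = int(hydroxyls[rng.integers(len(hydroxyls))])
    sugar = Chem.MolFromSmiles(_SUGAR_FRAGMENT)
    combined = Chem.RWMol(rdmolops.CombineMols(mol, sugar))
    anomeric = mol.GetNumAtoms()  # first sugar atom
    combined.AddBond(o_idx, anomeric, Chem.BondType.SINGLE)
    product = combined.GetMol()
    Chem.SanitizeMol(product)
    return product


def _decorate_aromatic(mol: Chem.Mol, rng: np.random.Generator,
                       max_substituents: int = 2,
                       mw_cap: float | None = None) -> Chem.Mol:
    """Randomly substitute aromatic C-H positions with small groups."""
    n_sub = int(rng.integers(0, max_substituents + 1))
    for _ in range(n_sub):
        sites = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
        ]
        if not sites:
            break
        frag_smiles = _AROMATIC_SUBSTITUENTS[rng.integers(len(_AROMATIC_SUBSTITUENTS))]
        frag = Chem.MolFromSmiles(frag_smiles)
        if mw_cap is not None and Descriptors.MolWt(mol) + Descriptors.MolWt(frag) > mw_cap:
            break
        site = int(sites[rng.integers(len(sites))])
        combined = Chem.RWMol(rdmolops.CombineMols(mol, frag))
        combined.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
        candidate = combined.GetMol()
        try:
            Chem.SanitizeMol(candidate)
        except Exception:
            continue
        mol = candidate
    return mol


# ---------------------------------------------------------------------------
# Per-class generators
# ---------------------------------------------------------------------------

def _make_plant(rng: np.random.Generator, glyco_prob: float) -> str:
    core = PLANT_SCAFFOLDS[rng.integers(len(PLANT_SCAFFOLDS))]
    mol = Chem.MolFromSmiles(core)
    mol = _decorate_aromatic(mol, rng)
    if rng.random() < glyco_prob:
        mol = _glycosylate(mol, rng)
    return Chem.MolToSmiles(mol)


def _make_fungal(rng: np.random.Generator, small_fraction: float,
                 glyco_prob: float) -> str:
    if rng.random() < small_fraction:
        core = FUNGAL_SMALL_SCAFFOLDS[rng.integers(len(FUNGAL_SMALL_SCAFFOLDS))]
        mol = Chem.MolFromSmiles(core)
        # stay below the small-molecule MW boundary
        mol = _decorate_aromatic(mol, rng, max_substituents=1, mw_cap=200.0)
        return Chem.MolToSmiles(mol)
    core = FUNGAL_MID_SCAFFOLDS[rng.integers(len(FUNGAL_MID_SCAFFOLDS))]
    mol = Chem.MolFromSmiles(core)
    mol = _decorate_aromatic(mol, rng)
    if rng.random() < glyco_prob:
        mol = _glycosylate(mol, rng)
    return Chem.MolToSmiles(mol)


def _make_bacterial(rng: np.random.Generator, length_range: tuple[int, int],
                    cyclic_prob: float, glyco_prob: float) -> str:
    lo, hi = length_range
    # cyclic dipeptides cannot embed the dipeptide SMARTS (the terminal N
    # would have to reuse the first match atom), so cycles need >= 3 residues
    length = int(rng.integers(lo, hi + 1))
    cyclic = length >= 3 and rng.random() < cyclic_prob
    sequence = [AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))] for _ in range(length)]
    mol = Chem.MolFromSmiles(assemble_peptide(sequence, cyclic))
    if rng.random() < glyco_prob:
        mol = _glycosylate(mol, rng)
    return Chem.MolToSmiles(mol)


def generate_dataset(config: SynthConfig = SynthConfig()) -> list[LabeledMolecule]:
    """Generate 3 x n_per_class labeled molecules, grouped by class.

    Deterministic: identical configs produce identical lists. Each class
    draws from its own RNG substream so changing one class parameter does
    not reshuffle the others.
    """
    streams = np.random.SeedSequence(config.seed).spawn(len(ORIGINS))
    molecules: list[LabeledMolecule] = []
    for origin, stream in zip(ORIGINS, streams):
        rng = np.random.default_rng(stream)
        for _ in range(config.n_per_class):
            if origin == "plant":
                smiles = _make_plant(rng, config.glycosylation_prob_plant)
            elif origin == "fungi":
                smiles = _make_fungal(
                    rng, config.small_mol_fraction_fungal,
                    config.glycosylation_prob_other,
                )
            else:
                smiles = _make_bacterial(
                    rng, config.peptide_length_range,
                    config.cyclic_peptide_prob, config.glycosylation_prob_other,
                )
            molecules.append(LabeledMolecule(smiles=smiles, origin=origin))
    return molecules


# ---------------------------------------------------------------------------
# Raw-record synthesis and the hand-built curation fixture
# ---------------------------------------------------------------------------

_TAXONOMY_TEMPLATES = {
    "plant": ("plants", "plant", "Viridiplantae, plants"),
    "fungi": ("fungi", "Aspergillus flavus, fungi", "fungi, endophyte"),
    "bacteria": ("bacteria", "Bacillus subtilis, bacteria", "actinobacteria, soil"),
}


def dataset_to_records(molecules, config: SynthConfig = SynthConfig()) -> pd.DataFrame:
    """Tabulate a generated dataset as raw records the curation stage accepts.

    Taxonomy strings and DOIs are synthesized deterministically so the
    DOI filter and origin resolution can run end to end on synthetic data.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    rows = []
    for i, lm in enumerate(molecules):
        templates = _TAXONOMY_TEMPLATES[lm.origin]
        rows.append(
            {
                "id": f"SYN{i:06d}",
                "smiles": lm.smiles,
                "taxonomy": templates[rng.integers(len(templates))],
                "doi": f"10.5281/synth.{i:06d}",
                "origin": lm.origin,
            }
        )
    return pd.DataFrame(rows)


def write_dataset_csv(path, config: SynthConfig = SynthConfig()) -> pd.DataFrame:
    df = dataset_to_records(generate_dataset(config), config)
    df.to_csv(path, index=False, encoding="utf-8")
    return df


def write_dataset_sdf(path, config: SynthConfig = SynthConfig()) -> None:
    """SDF export with id/taxonomy/doi/origin as tags."""
    df = dataset_to_records(generate_dataset(config), config)
    writer = Chem.SDWriter(str(path))
    try:
        for _, row in df.iterrows():
            mol = Chem.MolFromSmiles(row["smiles"])
            mol.SetProp("id", row["id"])
            mol.SetProp("taxonomy", row["taxonomy"])
            mol.SetProp("doi", row["doi"])
            mol.SetProp("origin", row["origin"])
            writer.write(mol)
    finally:
        writer.close()


@dataclass(frozen=True)
class FixtureRecord:
    """A raw record with its expected curation outcome."""

    id: str
    smiles: str
    taxonomy: str
    doi: str
    expected_kept: bool          # survives the DOI filter
    expected_origin: str         # resolve_origin(taxonomy)
    expected_selected: bool      # in the three-class subset

    def as_record_dict(self) -> dict:
        return {"id": self.id, "smiles": self.smiles,
                "taxonomy": self.taxonomy, "doi": self.doi}


_GOOD_DOI = "10.5281/fixture.0001"


def generate_curation_fixture() -> list[FixtureRecord]:
    """A fixed, hand-built set of raw records exercising every curation rule.

    Covers: each origin keyword, case-insensitivity and substring matching,
    every pairwise priority decision the three-class subset depends on,
    unmatched taxonomy, and the 10-character DOI filter (missing, short,
    and whitespace-padded DOIs). Identical on every call.
    """
    f = FixtureRecord
    return [
        f("FIX01", "CCO", "plant", _GOOD_DOI, True, "plant", True),
        f("FIX02", "CCO", "plants", _GOOD_DOI, True, "plant", True),
        f("FIX03", "CCO", "fungi", _GOOD_DOI, True, "fungi", True),
        f("FIX04", "CCO", "Aspergillus niger", _GOOD_DOI, True, "fungi", True),
        f("FIX05", "CCO", "bacteria", _GOOD_DOI, True, "bacteria", True),
        f("FIX06", "CCO", "Bacillus subtilis", _GOOD_DOI, True, "bacteria", True),
        f("FIX07", "CCO", "cyanobacta", _GOOD_DOI, True, "bacteria", True),
        f("FIX08", "CCO", "plants, bacteria", _GOOD_DOI, True, "bacteria", True),
        f("FIX09", "CCO", "aspergillus, plant", _GOOD_DOI, True, "fungi", True),
        f("FIX10", "CCO", "human, plant", _GOOD_DOI, True, "human", False),
        f("FIX11", "CCO", "marine, fungi", _GOOD_DOI, True, "fungi", True),
        f("FIX12", "CCO", "animal, marine", _GOOD_DOI, True, "animal", False),
        f("FIX13", "CCO", "marine sponge", _GOOD_DOI, True, "marine", False),
        f("FIX14", "CCO", "coral reef", _GOOD_DOI, True, "unresolved", False),
        f("FIX15", "CCO", "plants", "", False, "plant", False),
        f("FIX16", "CCO", "plants", "12345678", False, "plant", False),
        f("FIX17", "CCO", "plants", "   10.1/x   ", False, "plant", False),
    ]


def fixture_records_dataframe() -> pd.DataFrame:
    return pd.DataFrame([r.as_record_dict() for r in generate_curation_fixture()])
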
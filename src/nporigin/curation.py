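"""Record curation: DOI filtering, origin resolution, molecular profiling.

Natural-product databases annotate each entry with a free-text taxonomy
string and a literature reference. This module turns such raw records into
a clean three-class (plant / fungi / bacteria) dataset:

1. keep only entries whose DOI string is at least 10 characters long,
2. resolve the free-text taxonomy to an origin label by keyword matching
   with a fixed priority order for multi-origin annotations,
3. compute physico-chemical descriptors and flag glycosides and peptides by
   SMARTS substructure search,
4. assign each molecule a single category from an ordered predicate list.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .chem import parse_smiles

# Keyword sets matched against comma-split, lower-cased taxonomy tokens.
# The three retained classes use the published keyword lists; human/animal/
# marine exist only so the priority order below is well-defined.
ORIGIN_KEYWORDS: Mapping[str, frozenset[str]] = {
    "human": frozenset({"human", "homo"}),
    "animal": frozenset({"animal", "animals"}),
    "bacteria": frozenset({"bacteria", "bacillus", "bacta"}),
    "fungi": frozenset({"fungi", "aspergillus"}),
    "plant": frozenset({"plant", "plants"}),
    "marine": frozenset({"marine"}),
}

#: Resolution order when a taxonomy annotation matches several origins.
ORIGIN_PRIORITY: tuple[str, ...] = (
    "human",
    "animal",
    "bacteria",
    "fungi",
    "plant",
    "marine",
)

UNRESOLVED = "unresolved"
THREE_CLASSES: tuple[str, ...] = ("plant", "fungi", "bacteria")

MIN_DOI_LENGTH = 10

# Dipeptide: two consecutive amide units on alpha carbons, terminated by O or N.
PEPTIDE_SMARTS = (
    "[NX3,NX4+][CH1,CH2][CX3](=[OX1])[NX3,NX4+][CH1,CH2][CX3](=[OX1])[O,N]"
)
# Glycoside: cyclic N- or O-acetal (anomeric ring CH carrying an exocyclic O/N).
GLYCOSIDE_SMARTS = "[CR][OR][CHR]([OR0,NR0])[CR]"

_PEPTIDE_PATTERN = Chem.MolFromSmarts(PEPTIDE_SMARTS)
_GLYCOSIDE_PATTERN = Chem.MolFromSmarts(GLYCOSIDE_SMARTS)

#: Category labels in priority order (first matching predicate wins).
CATEGORIES: tuple[str, ...] = (
    "glycoside",
    "peptide",
    "high_MW",
    "high_Fsp3",
    "low_Fsp3",
    "low_MW",
    "none",
)


@dataclass(frozen=True)
class NPRecord:
    """One natural-product database entry."""

    id: str
    smiles: str
    taxonomy_raw: str
    doi: str
    origin: str = UNRESOLVED


@dataclass(frozen=True)
class MoleculeProfile:
    """Computed descriptors and substructure flags for one molecule."""

    mw: float          # average-isotope molecular weight, Da
    fsp3: float        # sp3 carbons / total carbons, in [0, 1]
    alogp: float       # Crippen atomic-contribution logP
    hbd: int
    hba: int
    tpsa: float        # topological polar surface area, A^2
    n_carbon: int
    n_oxygen: int
    n_nitrogen: int
    n_atoms: int       # heavy atoms
    n_bonds: int
    is_glycoside: bool
    is_peptide: bool
    category: str

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def filter_by_doi(records: Sequence) -> list:
    """Keep records whose (whitespace-trimmed) DOI has >= 10 characters.

    Accepts any objects with a ``doi`` attribute or ``"doi"`` key; a missing
    DOI counts as empty.
    """
    kept = []
    for rec in records:
        doi = rec.doi if hasattr(rec, "doi") else rec.get("doi", "")
        if doi is None:
            doi = ""
        if len(str(doi).strip()) >= MIN_DOI_LENGTH:
            kept.append(rec)
    return kept


def resolve_origin(taxonomy_raw: str) -> str:
    """Resolve a free-text taxonomy annotation to an origin label.

    The annotation is split on commas; each trimmed, lower-cased token is
    tested for containment of every origin keyword. When tokens match more
    than one origin, the highest-priority origin wins
    (human > animal > bacteria > fungi > plant > marine). Returns
    ``"unresolved"`` when nothing matches.
    """
    if taxonomy_raw is None:
        return UNRESOLVED
    tokens = [t.strip().lower() for t in str(taxonomy_raw).split(",")]
    matched = set()
    for token in tokens:
        if not token:
            continue
        for origin, keywords in ORIGIN_KEYWORDS.items():
            if any(kw in token for kw in keywords):
                matched.add(origin)
    for origin in ORIGIN_PRIORITY:
        if origin in matched:
            return origin
    return UNRESOLVED


def select_three_class_subset(records: Iterable[NPRecord]) -> list[NPRecord]:
    """Keep only records resolved to plant, fungi, or bacteria (order kept)."""
    return [r for r in records if r.origin in THREE_CLASSES]


def match_peptide(smiles: str, record_id: str | None = None) -> bool:
    """True iff the molecule contains the dipeptide substructure."""
    return parse_smiles(smiles, record_id).HasSubstructMatch(_PEPTIDE_PATTERN)


def match_glycoside(smiles: str, record_id: str | None = None) -> bool:
    """True iff the molecule contains the cyclic N-/O-acetal substructure."""
    return parse_smiles(smiles, record_id).HasSubstructMatch(_GLYCOSIDE_PATTERN)


def categorize(
    *,
    is_glycoside: bool,
    is_peptide: bool,
    mw: float,
    fsp3: float,
) -> str:
    """First matching category in the fixed priority order.

    glycoside > peptide > high_MW (MW >= 800) > high_Fsp3 (Fsp3 >= 0.8)
    > low_Fsp3 (Fsp3 <= 0.2) > low_MW (MW <= 200) > none. Boundary values
    belong to the bin named by the comparison (ties go to the flagged bin).
    """
    if is_glycoside:
        return "glycoside"
    if is_peptide:
        return "peptide"
    if mw >= 800:
        return "high_MW"
    if fsp3 >= 0.8:
        return "high_Fsp3"
    if fsp3 <= 0.2:
        return "low_Fsp3"
    if mw <= 200:
        return "low_MW"
    return "none"


def compute_profile(smiles: str, record_id: str | None = None) -> MoleculeProfile:
    """Descriptors, substructure flags and category for one molecule.

    MW is the standard average-isotope molecular weight; AlogP uses the
    Crippen atomic-contribution method; Fsp3 is the fraction of sp3 carbon
    atoms. Atom counts refer to heavy atoms only.
    """
    mol = parse_smiles(smiles, record_id)
    mw = Descriptors.MolWt(mol)
    fsp3 = rdMolDescriptors.CalcFractionCSP3(mol)
    is_gly = mol.HasSubstructMatch(_GLYCOSIDE_PATTERN)
    is_pep = mol.HasSubstructMatch(_PEPTIDE_PATTERN)
    return MoleculeProfile(
        mw=mw,
        fsp3=fsp3,
        alogp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        n_carbon=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6),
        n_oxygen=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8),
        n_nitrogen=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7),
        n_atoms=mol.GetNumAtoms(),
        n_bonds=mol.GetNumBonds(),
        is_glycoside=is_gly,
        is_peptide=is_pep,
        category=categorize(is_glycoside=is_gly, is_peptide=is_pep, mw=mw, fsp3=fsp3),
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {
    "id": "id",
    "smiles": "smiles",
    "taxonomy": "taxonomy",
    "doi": "doi",
}


def read_records(
    path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[NPRecord]:
    """Read raw records from CSV/TSV (column names configurable) or SDF."""
    path = str(path)
    if path.lower().endswith(".sdf"):
        return _read_records_sdf(path, columns)
    cols = dict(DEFAULT_COLUMNS, **(columns or {}))
    if sep is None:
        sep = "\t" if path.lower().endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return [
        NPRecord(
            id=row[cols["id"]],
            smiles=row[cols["smiles"]],
            taxonomy_raw=row.get(cols["taxonomy"], ""),
            doi=row.get(cols["doi"], ""),
        )
        for _, row in df.iterrows()
    ]


def _read_records_sdf(path: str, columns: Mapping[str, str] | None) -> list[NPRecord]:
    cols = dict(DEFAULT_COLUMNS, **(columns or {}))
    records = []
    supplier = Chem.SDMolSupplier(path)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        props = mol.GetPropsAsDict()
        records.append(
            NPRecord(
                id=str(props.get(cols["id"], f"sdf-{i}")),
                smiles=Chem.MolToSmiles(mol),
                taxonomy_raw=str(props.get(cols["taxonomy"], "")),
                doi=str(props.get(cols["doi"], "")),
            )
        )
    return records


def curate_records(
    records: Sequence[NPRecord],
    skip_unparseable: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Run the full curation funnel on raw records.

    DOI filter -> origin resolution -> three-class selection -> profiles.
    Returns the curated table (one row per kept record, profile columns
    appended) and the number of records skipped for unparseable SMILES.
    """
    kept = filter_by_doi(records)
    resolved = [
        dataclasses.replace(r, origin=resolve_origin(r.taxonomy_raw)) for r in kept
    ]
    selected = select_three_class_subset(resolved)
    rows, n_skipped = [], 0
    for rec in selected:
        try:
            profile = compute_profile(rec.smiles, rec.id)
        except Exception:
            if not skip_unparseable:
                raise
            n_skipped += 1
            continue
        row = {"id": rec.id, "smiles": rec.smiles, "origin": rec.origin,
               "taxonomy": rec.taxonomy_raw, "doi": rec.doi}
        row.update(profile.as_dict())
        rows.append(row)
    return pd.DataFrame(rows), n_skipped


def write_curated(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def read_curated(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
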
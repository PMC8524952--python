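"""Thin RDKit wrappers shared across the pipeline."""

from __future__ import annotations

from rdkit import Chem, RDLogger

from .errors import MoleculeParseError

# RDKit is chatty about kekulization/valence on stderr; errors are surfaced
# as exceptions instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


def parse_smiles(smiles: str, record_id: str | None = None) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`MoleculeParseError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise MoleculeParseError(str(smiles), record_id)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(smiles, record_id)
    return mol


def canonical_smiles(smiles: str, record_id: str | None = None) -> str:
    """Canonical (isomeric) SMILES of ``smiles``."""
    return Chem.MolToSmiles(parse_smiles(smiles, record_id))


def strip_stereo(mol: Chem.Mol) -> Chem.Mol:
    """Return a copy of ``mol`` with all stereochemistry removed.

    Mirrors what the online predictor does to a query before
    fingerprinting, so that predictions depend on the molecular graph only.
    """
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    return flat
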
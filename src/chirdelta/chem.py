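"""SMILES-level stereochemistry operations and dataset curation.

The unit of analysis throughout the package is a molecule with exactly one
tetrahedral stereocenter, written as a canonical isomeric SMILES in which
the center carries an ``@`` (anticlockwise) or ``@@`` (clockwise) parity
tag.  Two such molecules that differ only in the parity of that center are
an enantiomer pair; their shared stereo-depleted canonical SMILES is the
pair key used everywhere downstream.

This module provides the elementary stereo operators (enantiomer inversion,
stereo depletion, CIP labeling, CIP-aligned re-tagging) and the curation
pipeline that turns a raw table of SMILES + retention times into a clean
list of :class:`MoleculeRecord` objects grouped into complete enantiomer
pairs, with every dropped row logged under a reason code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdCIPLabeler

from .errors import MultiCenterError, NoStereocenterError, ParseError

RDLogger.DisableLog("rdApp.error")

#: Element whitelist applied during curation (hydrogen plus common
#: organic/halogen elements; everything else, e.g. Si or metals, is dropped).
ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"}
)

#: Stereo-tag classes: AT = single "@" (anticlockwise), ATAT = "@@" (clockwise).
STEREO_TAGS = ("AT", "ATAT")

#: CIP absolute-configuration labels.
CIP_LABELS = ("R", "S")

_WHITESPACE = re.compile(r"\s+")


@dataclass
class MoleculeRecord:
    """One curated molecule.

    Attributes
    ----------
    smiles_raw : str
        The SMILES string exactly as read from the input table.
    smiles_canonical : str
        Canonical isomeric SMILES (toolkit canonicalization).
    stereo_tag : str
        ``"AT"`` when the canonical SMILES carries a single ``@``,
        ``"ATAT"`` for ``@@``.
    cip_label : str
        CIP absolute configuration, ``"R"`` or ``"S"``.
    pair_key : str
        Stereo-depleted canonical SMILES; identical for the two members of
        an enantiomer pair.
    retention_time : float, optional
        Chromatographic retention time in minutes.
    experiment_id : str, optional
        Opaque identifier of the experiment the retention time came from.
        Retention times are only comparable within one experiment.
    elution_label : str, optional
        ``"First"`` or ``"Last"``; assigned by :func:`dataset.label_elution`.
    """

    smiles_raw: str
    smiles_canonical: str
    stereo_tag: str
    cip_label: str
    pair_key: str
    retention_time: Optional[float] = None
    experiment_id: Optional[str] = None
    elution_label: Optional[str] = None

    def copy(self) -> "MoleculeRecord":
        return replace(self)


def _parse(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, stripping any internal whitespace first.

    Whitespace inside printed SMILES (e.g. ``"(= O)"`` from typesetting)
    is removed so published strings round-trip.
    """
    if not isinstance(smiles, str):
        raise ParseError(f"expected a SMILES string, got {type(smiles).__name__}")
    cleaned = _WHITESPACE.sub("", smiles)
    if not cleaned:
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(cleaned)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def _tetra_atoms(mol: Chem.Mol) -> list:
    return [
        a
        for a in mol.GetAtoms()
        if a.GetChiralTag()
        in (
            Chem.ChiralType.CHI_TETRAHEDRAL_CW,
            Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
        )
    ]


def canonicalize(smiles: str) -> str:
    """Return the canonical isomeric SMILES for *smiles*.

    Deterministic and idempotent; tetrahedral parity tags are preserved.
    Raises :class:`ParseError` on unparseable input.
    """
    return Chem.MolToSmiles(_parse(smiles))


def stereo_tag_of(smiles: str) -> str:
    """Classify a single-stereocenter SMILES by its parity tag.

    Returns ``"ATAT"`` when the string contains ``@@``, ``"AT"`` when it
    contains a lone ``@``.  Raises :class:`NoStereocenterError` for tag-free
    strings and ``ValueError`` when both tag classes occur (more than one
    center — outside this package's domain).
    """
    has_atat = "@@" in smiles
    has_at = re.search(r"(?<!@)@(?!@)", smiles) is not None
    if has_atat and has_at:
        raise ValueError(f"mixed @ and @@ tags in {smiles!r}: more than one center")
    if has_atat:
        return "ATAT"
    if has_at:
        return "AT"
    raise NoStereocenterError(f"no tetrahedral parity tag in {smiles!r}")


def invert_enantiomer(smiles: str) -> str:
    """Return the canonical SMILES of the opposite enantiomer.

    Every tetrahedral parity is inverted and the result re-canonicalized.
    Involutive on canonical forms; the stereo-depleted forms of input and
    output coincide.  Raises :class:`NoStereocenterError` on achiral input.
    """
    mol = _parse(smiles)
    atoms = _tetra_atoms(mol)
    if not atoms:
        raise NoStereocenterError(f"no tetrahedral stereocenter in {smiles!r}")
    for atom in atoms:
        atom.InvertChirality()
    return Chem.MolToSmiles(mol)


def strip_stereo(smiles: str) -> str:
    """Return the stereo-depleted canonical SMILES (the pair key).

    All tetrahedral and double-bond stereo descriptors are removed before
    canonicalization.  Idempotent, and invariant under enantiomer inversion.
    """
    mol = _parse(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def assign_cip(smiles: str) -> str:
    """Return the CIP label (``"R"`` or ``"S"``) of the single stereocenter.

    Delegates to the toolkit's full CIP implementation (priority rules, not
    parity heuristics).  Raises :class:`NoStereocenterError` /
    :class:`MultiCenterError` when the number of tetrahedral centers is not
    exactly one.
    """
    mol = _parse(smiles)
    atoms = _tetra_atoms(mol)
    if not atoms:
        raise NoStereocenterError(f"no tetrahedral stereocenter in {smiles!r}")
    if len(atoms) > 1:
        raise MultiCenterError(f"{len(atoms)} stereocenters in {smiles!r}")
    rdCIPLabeler.AssignCIPLabels(mol)
    atom = atoms[0]
    if not atom.HasProp("_CIPCode"):
        raise NoStereocenterError(
            f"stereocenter in {smiles!r} has no CIP label (pseudo-asymmetric?)"
        )
    return atom.GetProp("_CIPCode")


#: Tag convention used by :func:`relabel_cip_aligned`: "@" for S, "@@" for R.
CIP_ALIGNED_TAG = {"S": "AT", "R": "ATAT"}


def relabel_cip_aligned(smiles: str, max_random_tries: int = 500) -> str:
    """Rewrite *smiles* so its parity tag matches the CIP convention @=S, @@=R.

    The SMILES parity tag depends on the order in which neighbors of the
    center are written, so the *same* molecule can legally be written with
    either tag.  This function returns a SMILES of the same molecule (same
    constitution, same CIP label) whose tag class equals
    ``CIP_ALIGNED_TAG[cip]``.  When the canonical form is already aligned it
    is returned unchanged; otherwise deterministic atom re-rootings (and, as
    a last resort, seeded atom renumberings) are searched for a rewrite with
    the desired tag.
    """
    can = canonicalize(smiles)
    cip = assign_cip(can)
    want = CIP_ALIGNED_TAG[cip]
    if stereo_tag_of(can) == want:
        return can
    mol = Chem.MolFromSmiles(can)
    for root in range(mol.GetNumAtoms()):
        alt = Chem.MolToSmiles(mol, rootedAtAtom=root)
        if stereo_tag_of(alt) == want and Chem.MolToSmiles(Chem.MolFromSmiles(alt)) == can:
            return alt
    rng = np.random.default_rng(0)
    n = mol.GetNumAtoms()
    for _ in range(max_random_tries):
        perm = [int(i) for i in rng.permutation(n)]
        alt = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
        if stereo_tag_of(alt) == want and Chem.MolToSmiles(Chem.MolFromSmiles(alt)) == can:
            return alt
    raise RuntimeError(f"could not find a CIP-aligned rewrite of {can!r}")


def _stereo_profile(mol: Chem.Mol):
    """Count stereo features: (specified tetrahedral, unspecified tetrahedral,
    specified bond stereo, potential-but-unspecified bond stereo)."""
    spec_tet = unspec_tet = spec_bond = unspec_bond = 0
    for si in Chem.FindPotentialStereo(mol):
        specified = si.specified == Chem.StereoSpecified.Specified
        if si.type == Chem.StereoType.Atom_Tetrahedral:
            if specified:
                spec_tet += 1
            else:
                unspec_tet += 1
        else:
            if specified:
                spec_bond += 1
            else:
                unspec_bond += 1
    return spec_tet, unspec_tet, spec_bond, unspec_bond


def _stereo_reason(mol: Chem.Mol) -> Optional[str]:
    """Return a rejection reason for *mol*'s stereo profile, or None if kept.

    Kept: exactly one assigned tetrahedral center, no other assigned or
    assignable stereo except potential (unassigned) double-bond stereo,
    which is tolerated because it is pervasive in real libraries.
    """
    spec_tet, unspec_tet, spec_bond, _ = _stereo_profile(mol)
    if spec_tet == 0:
        if unspec_tet or spec_bond:
            return "stereo_type"
        return "no_stereocenter"
    if spec_tet > 1:
        return "multi_stereocenter"
    if unspec_tet or spec_bond:
        return "stereo_type"
    return None


def _element_ok(mol: Chem.Mol) -> bool:
    return all(a.GetSymbol() in ALLOWED_ELEMENTS for a in mol.GetAtoms())


REJECT_REASONS = (
    "flagged",
    "parse",
    "element",
    "no_stereocenter",
    "multi_stereocenter",
    "stereo_type",
    "inconsistent_duplicate",
    "duplicate",
    "orphan",
)


def curate(
    frame: pd.DataFrame,
    smiles_column: str = "smiles",
    drop_flag_column: Optional[str] = None,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Apply the curation filters to a raw table and build molecule records.

    Filters, in order:

    1. rows marked in *drop_flag_column* (generic hook for upstream flags
       such as unclear major/minor enantiomer annotations) — ``flagged``;
    2. unparseable SMILES — ``parse``;
    3. elements outside :data:`ALLOWED_ELEMENTS` — ``element``;
    4. stereo profile: anything but exactly one assigned tetrahedral center
       — ``no_stereocenter`` / ``multi_stereocenter`` / ``stereo_type``;
    5. duplicate canonical SMILES: conflicting annotations drop every
       occurrence (``inconsistent_duplicate``); consistent duplicates keep
       the first occurrence (``duplicate``);
    6. molecules whose enantiomer partner did not survive — ``orphan``.

    Returns ``(records, rejections)`` where *rejections* has columns
    ``row``, ``smiles``, ``reason``.  Rows are never dropped silently.
    """
    required = {smiles_column}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"input table lacks column(s): {sorted(missing)}")

    rejections: list[tuple[int, str, str]] = []
    keep: dict[int, dict] = {}

    for row_idx, row in frame.reset_index(drop=True).iterrows():
        raw = row[smiles_column]
        if drop_flag_column is not None and bool(row.get(drop_flag_column, False)):
            rejections.append((row_idx, str(raw), "flagged"))
            continue
        try:
            mol = _parse(raw)
        except ParseError:
            rejections.append((row_idx, str(raw), "parse"))
            continue
        if not _element_ok(mol):
            rejections.append((row_idx, str(raw), "element"))
            continue
        can = Chem.MolToSmiles(mol)
        mol_can = Chem.MolFromSmiles(can)
        reason = _stereo_reason(mol_can)
        if reason is not None:
            rejections.append((row_idx, str(raw), reason))
            continue
        rt = row.get("retention_time")
        rt = None if pd.isna(rt) else float(rt)
        exp = row.get("experiment_id")
        exp = None if pd.isna(exp) else str(exp)
        elu = row.get("elution_label")
        elu = None if pd.isna(elu) else str(elu)
        keep[row_idx] = dict(
            raw=str(raw), canonical=can, retention_time=rt,
            experiment_id=exp, elution_label=elu,
        )

    # duplicate handling on canonical SMILES
    by_can: dict[str, list[int]] = {}
    for idx, info in keep.items():
        by_can.setdefault(info["canonical"], []).append(idx)
    for can, idxs in by_can.items():
        if len(idxs) == 1:
            continue
        infos = [keep[i] for i in idxs]
        labels = {x["elution_label"] for x in infos if x["elution_label"] is not None}
        inconsistent = len(labels) > 1
        if not inconsistent:
            # same molecule reported twice in one experiment with different
            # retention times is contradictory
            by_exp: dict[str, set[float]] = {}
            for x in infos:
                if x["experiment_id"] is not None and x["retention_time"] is not None:
                    by_exp.setdefault(x["experiment_id"], set()).add(x["retention_time"])
            inconsistent = any(len(ts) > 1 for ts in by_exp.values())
        if inconsistent:
            for i in idxs:
                rejections.append((i, keep[i]["raw"], "inconsistent_duplicate"))
                del keep[i]
        else:
            for i in sorted(idxs)[1:]:
                rejections.append((i, keep[i]["raw"], "duplicate"))
                del keep[i]

    # pair completeness: both enantiomers must survive
    by_pair: dict[str, list[int]] = {}
    pair_key_of: dict[int, str] = {}
    for idx in sorted(keep):
        pk = strip_stereo(keep[idx]["canonical"])
        pair_key_of[idx] = pk
        by_pair.setdefault(pk, []).append(idx)
    for pk, idxs in by_pair.items():
        cans = {keep[i]["canonical"] for i in idxs}
        if len(idxs) != 2 or len(cans) != 2:
            for i in idxs:
                rejections.append((i, keep[i]["raw"], "orphan"))
                del keep[i]

    records = []
    for idx in sorted(keep):
        info = keep[idx]
        can = info["canonical"]
        records.append(
            MoleculeRecord(
                smiles_raw=info["raw"],
                smiles_canonical=can,
                stereo_tag=stereo_tag_of(can),
                cip_label=assign_cip(can),
                pair_key=pair_key_of[idx],
                retention_time=info["retention_time"],
                experiment_id=info["experiment_id"],
                elution_label=info["elution_label"],
            )
        )
    rejection_frame = pd.DataFrame(rejections, columns=["row", "smiles", "reason"])
    return records, rejection_frame


def records_to_frame(records: Iterable[MoleculeRecord]) -> pd.DataFrame:
    """Tabulate records as the curated-output CSV layout."""
    return pd.DataFrame(
        [
            {
                "smiles": r.smiles_raw,
                "smiles_canonical": r.smiles_canonical,
                "stereo_tag": r.stereo_tag,
                "cip_label": r.cip_label,
                "pair_key": r.pair_key,
                "retention_time": r.retention_time,
                "experiment_id": r.experiment_id,
                "elution_label": r.elution_label,
            }
            for r in records
        ]
    )
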
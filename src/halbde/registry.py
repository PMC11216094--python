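"""Chemical space of cyclic hypervalent halogen(III) reagents.

A reagent is a combination of a cyclic skeleton (a ring framework that holds
the halogen center, labelled 1-6), a halogen center (I, Br, or Cl in the +3
formal oxidation state), and a transfer group (the substituent the reagent
delivers, labelled a-t plus extensions).  Skeleton templates carry the
halogen position as an atom-mapped iodine placeholder (``[I:1]``) and the
group attachment as a mapped wildcard (``[*:2]``); transfer-group fragments
carry a single mapped wildcard (``[*:1]``).  Substitution is performed on the
parsed molecule, never by string splicing.

Valence convention
------------------
Neutral three-coordinate Br and Cl violate default SMILES valence rules, so
every structure in this package is parsed with relaxed valence checking
(sanitization minus the valence-property check) and written back with RDKit's
canonical writer.  The same convention is applied to all three halogens so
that molecular graphs are mutually consistent; no claim about physical bond
orders at the hypervalent center is implied.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import AssemblyError, RegistryLookupError, SmilesParseError

RDLogger.DisableLog("rdApp.*")

HALOGENS = ("I", "Br", "Cl")

_RELAXED_OPS = Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string under the relaxed hypervalent-valence convention.

    Raises
    ------
    SmilesParseError
        If the string has invalid syntax or fails (relaxed) sanitization.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    try:
        mol.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(mol, _RELAXED_OPS)
    except Exception as exc:  # pragma: no cover - rdkit raises many types
        raise SmilesParseError(f"sanitization failed for {smiles!r}: {exc}") from exc
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES under the relaxed convention (idempotent)."""
    return Chem.MolToSmiles(parse_smiles(smiles))


@dataclass(frozen=True)
class SkeletonTemplate:
    skeleton_id: int
    template_smiles: str
    description: str = ""


@dataclass(frozen=True)
class TransferGroup:
    group_id: str
    group_smiles: str
    label: str


@dataclass(frozen=True)
class Reagent:
    """One skeleton x halogen x transfer-group combination."""

    skeleton_id: int
    halogen: str
    group_id: str
    smiles: str

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.skeleton_id, self.halogen, self.group_id)

    @property
    def name(self) -> str:
        return f"{self.skeleton_id}-{self.halogen}-{self.group_id}"


class ReagentRegistry:
    """Skeleton templates and transfer groups, with structure assembly.

    The default registry is loaded from the packaged TSV files
    (``data/skeletons.tsv``, ``data/groups.tsv``); chemists can extend the
    space by pointing the constructor at edited copies.
    """

    def __init__(self, skeletons: Iterable[SkeletonTemplate],
                 groups: Iterable[TransferGroup]):
        self.skeletons: dict[int, SkeletonTemplate] = {}
        for sk in skeletons:
            if sk.skeleton_id in self.skeletons:
                raise ValueError(f"duplicate skeleton_id {sk.skeleton_id}")
            self.skeletons[sk.skeleton_id] = sk
        self.groups: dict[str, TransferGroup] = {}
        self._label_to_id: dict[str, str] = {}
        for g in groups:
            if g.group_id in self.groups:
                raise ValueError(f"duplicate group_id {g.group_id!r}")
            self.groups[g.group_id] = g
            self._label_to_id.setdefault(g.label, g.group_id)

    @classmethod
    def default(cls) -> "ReagentRegistry":
        base = resources.files("halbde.data")
        sk = pd.read_csv(base / "skeletons.tsv", sep="\t")
        gr = pd.read_csv(base / "groups.tsv", sep="\t")
        return cls(
            (SkeletonTemplate(int(r.skeleton_id), r.template_smiles, r.description)
             for r in sk.itertuples()),
            (TransferGroup(str(r.group_id), r.group_smiles, str(r.label))
             for r in gr.itertuples()),
        )

    # -- lookups ---------------------------------------------------------
    def skeleton(self, skeleton_id: int) -> SkeletonTemplate:
        try:
            return self.skeletons[int(skeleton_id)]
        except (KeyError, ValueError):
            raise RegistryLookupError(f"unknown skeleton_id: {skeleton_id!r}") from None

    def group(self, group_id: str) -> TransferGroup:
        """Look up a transfer group by id (``"a"``) or printed label (``"F"``)."""
        if group_id in self.groups:
            return self.groups[group_id]
        if group_id in self._label_to_id:
            return self.groups[self._label_to_id[group_id]]
        raise RegistryLookupError(f"unknown group_id: {group_id!r}")

    # -- assembly --------------------------------------------------------
    def assemble_smiles(self, template: SkeletonTemplate, halogen: str,
                        group: TransferGroup) -> str:
        """Substitute halogen and transfer group into a skeleton template.

        Returns the canonical SMILES of the assembled reagent; assembling the
        same inputs twice yields byte-identical strings.
        """
        if halogen not in HALOGENS:
            raise RegistryLookupError(f"unknown halogen: {halogen!r}")
        tmpl = Chem.MolFromSmiles(template.template_smiles, sanitize=False)
        frag = Chem.MolFromSmiles(group.group_smiles, sanitize=False)
        if tmpl is None or frag is None:
            raise AssemblyError(
                f"registry entry does not parse: template={template.template_smiles!r} "
                f"group={group.group_smiles!r}")

        combined = Chem.RWMol(Chem.CombineMols(tmpl, frag))
        center = attach_dummy = group_dummy = None
        for atom in combined.GetAtoms():
            if atom.GetAtomMapNum() == 1 and atom.GetAtomicNum() > 0:
                center = atom.GetIdx()
            elif atom.GetAtomMapNum() == 2 and atom.GetAtomicNum() == 0:
                attach_dummy = atom.GetIdx()
            elif atom.GetAtomMapNum() == 1 and atom.GetAtomicNum() == 0:
                group_dummy = atom.GetIdx()
        if center is None or attach_dummy is None or group_dummy is None:
            raise AssemblyError(
                f"template {template.template_smiles!r} / group "
                f"{group.group_smiles!r} lack the expected mapped placeholders")

        combined.GetAtomWithIdx(center).SetAtomicNum(
            Chem.GetPeriodicTable().GetAtomicNumber(halogen))
        combined.GetAtomWithIdx(center).SetAtomMapNum(0)
        group_attach = [n.GetIdx() for n in
                        combined.GetAtomWithIdx(group_dummy).GetNeighbors()]
        if len(group_attach) != 1:
            raise AssemblyError(
                f"group fragment {group.group_smiles!r} must have exactly one "
                "atom bonded to its attachment wildcard")
        combined.AddBond(center, group_attach[0], Chem.BondType.SINGLE)
        # remove higher index first so the lower one stays valid
        for idx in sorted((attach_dummy, group_dummy), reverse=True):
            combined.RemoveAtom(idx)

        raw = Chem.MolToSmiles(combined)
        try:
            return canonical_smiles(raw)
        except SmilesParseError as exc:
            raise AssemblyError(
                f"assembly of skeleton {template.skeleton_id} + {halogen} + "
                f"{group.group_id!r} produced an unparsable structure: {raw!r}"
            ) from exc

    def make_reagent(self, skeleton_id: int, halogen: str, group_id: str) -> Reagent:
        sk = self.skeleton(skeleton_id)
        gr = self.group(group_id)
        return Reagent(sk.skeleton_id, halogen, gr.group_id,
                       self.assemble_smiles(sk, halogen, gr))

    def enumerate_reagents(self, skeleton_ids: Sequence[int],
                           halogens: Sequence[str],
                           group_ids: Sequence[str]) -> list[Reagent]:
        """Cartesian product of the given ids, in (skeleton, halogen, group) order."""
        for h in halogens:
            if h not in HALOGENS:
                raise RegistryLookupError(f"unknown halogen: {h!r}")
        return [self.make_reagent(s, h, g)
                for s in skeleton_ids for h in halogens for g in group_ids]

    def to_sdf(self, reagents: Sequence[Reagent], path: str) -> None:
        """Export an enumerated library as SDF for inspection in external viewers."""
        writer = Chem.SDWriter(str(path))
        try:
            for r in reagents:
                mol = parse_smiles(r.smiles)
                mol.SetProp("_Name", r.name)
                writer.write(mol)
        finally:
            writer.close()
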
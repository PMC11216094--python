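"""Synthetic BDE tables and toy molecular libraries with known structure.

Every downstream stage — cross-halogen regression, scaling, splitting, GAT
training, descriptor ablation — can be exercised on data whose generating
process is known exactly.  Two generators are provided:

* :func:`generate_bde_table` emulates the linear cross-halogen structure of
  the real tables: an iodine BDE column drawn from a normal distribution,
  bromine and chlorine columns that are affine in the iodine value plus
  homoscedastic Gaussian noise, and optional uniformly-random missing cells.
  Output uses the exact fixture CSV schema, so every consumer is agnostic
  about real versus synthetic data.

* :func:`generate_toy_library` builds small parseable organic molecules with
  targets computed exactly by a documented closed-form rule on the atom
  composition, for model capacity and ablation-control tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .dataset import FIXTURE_COLUMNS, BDERecord
from .registry import parse_smiles


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating process for a synthetic BDE table.

    Defaults mirror the real homolytic table: a 5-skeleton x 20-group grid,
    published Br/Cl-on-I line coefficients, an iodine column matching the
    fixture's location/spread, and a residual scatter consistent with the
    moderate homolytic correlation.
    """

    n_skeletons: int = 5
    n_groups: int = 20
    slope_br: float = 0.89
    intercept_br: float = -13.85
    slope_cl: float = 0.76
    intercept_cl: float = -26.02
    iodine_mean: float = 54.0     # kcal/mol, homolytic I-column location
    iodine_sd: float = 13.0       # kcal/mol, homolytic I-column spread
    noise_sd: float = 3.0         # kcal/mol residual around the line
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.n_skeletons * self.n_groups < 3:
            raise ValueError("need at least 3 skeleton x group cells")


def generate_bde_table(spec: SyntheticSpec,
                       bde_type: str = "homolytic") -> pd.DataFrame:
    """Draw a synthetic BDE table in the fixture CSV schema.

    I ~ Normal(iodine_mean, iodine_sd) per (skeleton, group) cell;
    Br = slope_br * I + intercept_br + Normal(0, noise_sd), Cl analogous.
    Cells are masked missing (sentinel "dash") independently with
    probability ``missing_fraction``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for sk in range(1, spec.n_skeletons + 1):
        for gi in range(spec.n_groups):
            gid = f"g{gi:02d}"
            x = rng.normal(spec.iodine_mean, spec.iodine_sd)
            values = {
                "I": x,
                "Br": spec.slope_br * x + spec.intercept_br
                      + rng.normal(0.0, spec.noise_sd),
                "Cl": spec.slope_cl * x + spec.intercept_cl
                      + rng.normal(0.0, spec.noise_sd),
            }
            for hal in ("I", "Br", "Cl"):
                missing = rng.random() < spec.missing_fraction
                rows.append({
                    "skeleton_id": sk, "halogen": hal, "group_id": gid,
                    "group_label": gid.upper(),
                    "bde_kcal_mol": "" if missing else f"{values[hal]:.6f}",
                    "sentinel": "dash" if missing else "",
                })
    return pd.DataFrame(rows, columns=FIXTURE_COLUMNS)


def table_to_records(table: pd.DataFrame,
                     bde_type: str = "homolytic") -> list[BDERecord]:
    """Convert a generated table to records without a filesystem round-trip."""
    records = []
    for row in table.itertuples(index=False):
        missing = bool(row.sentinel)
        records.append(BDERecord(
            int(row.skeleton_id), row.halogen, row.group_id, row.group_label,
            bde_type, None if missing else float(row.bde_kcal_mol),
            missing, row.sentinel or None))
    return records


def write_bde_table(spec: SyntheticSpec, path: str | Path,
                    bde_type: str = "homolytic") -> None:
    generate_bde_table(spec, bde_type).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# toy molecular libraries
# ---------------------------------------------------------------------------

#: Closed-form composition -> pseudo-BDE rules.  Each maps a Counter of
#: element symbols (heavy atoms of the parsed molecule) to a target value.
RULES: dict[str, Callable[[Counter], float]] = {
    # linear in carbon and oxygen counts
    "composition_linear": lambda c: 10.0 * c["C"] + 5.0 * c["O"],
    # halogen-identity dominated, loosely shaped like the homolytic trend
    # I > Br > Cl, with a small size term
    "halogen_linear": lambda c: (30.0 * c["I"] + 18.0 * c["Br"]
                                 + 6.0 * c["Cl"] + 2.0 * c["C"]),
}

_BACKBONE = ("C", "C", "C", "O", "N", "S")
_SUBSTITUENTS = ("F", "Cl", "Br", "I", "O", "N", "C")


def generate_toy_library(n_molecules: int, rule: str | Callable[[Counter], float]
                         = "composition_linear", seed: int = 0
                         ) -> tuple[list[str], np.ndarray]:
    """Random small organics with targets computed exactly by ``rule``.

    Molecules are built atom-by-atom on an RDKit RWMol (a random-length
    chain of C/N/O/S with random halogen/heteroatom substituents, optionally
    closed into a ring), so every SMILES is valid by construction; targets
    are evaluated on the heavy-atom composition of the parsed molecule.
    Deterministic for a fixed seed.
    """
    rule_fn = RULES[rule] if isinstance(rule, str) else rule
    rng = np.random.default_rng(seed)
    smiles: list[str] = []
    targets: list[float] = []
    seen: set[str] = set()
    while len(smiles) < n_molecules:
        mol = Chem.RWMol()
        length = int(rng.integers(3, 9))
        chain = []
        for i in range(length):
            sym = _BACKBONE[rng.integers(len(_BACKBONE))] if i else "C"
            chain.append(mol.AddAtom(Chem.Atom(sym)))
            if i:
                mol.AddBond(chain[i - 1], chain[i], Chem.BondType.SINGLE)
        if length >= 5 and rng.random() < 0.3:
            mol.AddBond(chain[0], chain[-1], Chem.BondType.SINGLE)
        n_subs = int(rng.integers(0, 4))
        carbon_sites = [i for i in chain
                        if mol.GetAtomWithIdx(i).GetSymbol() == "C"]
        for _ in range(n_subs):
            site = carbon_sites[rng.integers(len(carbon_sites))]
            sub = mol.AddAtom(Chem.Atom(
                _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]))
            mol.AddBond(site, sub, Chem.BondType.SINGLE)
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            continue
        parsed = parse_smiles(smi)   # validity check under package convention
        seen.add(smi)
        comp = Counter(a.GetSymbol() for a in parsed.GetAtoms())
        smiles.append(smi)
        targets.append(float(rule_fn(comp)))
    return smiles, np.asarray(targets)
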
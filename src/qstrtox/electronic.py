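"""Conceptual-DFT global reactivity indices from frontier-orbital energies.

The quantum-chemical calculations themselves (geometry optimisation,
orbital energies, Hirshfeld charges) are external; this module ingests
their results and derives, via the Koopmans approximation, the global
indices of conceptual density-functional theory:

    I = -E_HOMO            ionisation potential
    A = -E_LUMO            electron affinity
    mu = -(I + A)/2        chemical potential
    eta = (I - A)/2        chemical hardness
    omega = mu^2 / (2 eta) electrophilicity
    gap = E_LUMO - E_HOMO

All energies in eV.  The alternative hardness convention eta = I - A
(a factor of two) is available through ``Conventions.hardness_factor``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from qstrtox.config import Conventions

logger = logging.getLogger(__name__)


@dataclass
class ElectronicRecord:
    id: str
    e_homo: Optional[float] = None   # eV
    e_lumo: Optional[float] = None   # eV
    I: Optional[float] = None        # ionisation potential, eV
    A: Optional[float] = None        # electron affinity, eV
    mu: Optional[float] = None       # chemical potential, eV
    eta: Optional[float] = None      # hardness, eV
    omega: Optional[float] = None    # electrophilicity, eV
    gap: Optional[float] = None      # E_LUMO - E_HOMO, eV
    qC: Optional[float] = None       # Hirshfeld charge of the carbonyl C, e


def conceptual_dft(e_homo: float, e_lumo: float,
                   conv: Conventions | None = None) -> ElectronicRecord:
    """Derive I, A, mu, eta, omega and the gap from orbital energies (eV).

    When the gap is non-positive (eta <= 0) the electrophilicity is
    undefined and returned as None with a warning.
    """
    conv = conv or Conventions()
    if not (math.isfinite(e_homo) and math.isfinite(e_lumo)):
        raise ValueError("orbital energies must be finite")
    I = -e_homo
    A = -e_lumo
    mu = -(I + A) / 2.0
    eta = (I - A) / 2.0 if conv.hardness_factor == "half" else I - A
    gap = e_lumo - e_homo
    if eta > 0:
        omega = mu * mu / (2.0 * eta)
    else:
        omega = None
        logger.warning("non-positive hardness (E_LUMO <= E_HOMO); "
                       "electrophilicity undefined")
    return ElectronicRecord(id="", e_homo=e_homo, e_lumo=e_lumo,
                            I=I, A=A, mu=mu, eta=eta, omega=omega, gap=gap)


def load_electronic_csv(path: str | Path,
                        conv: Conventions | None = None) -> pd.DataFrame:
    """Load per-compound electronic data.

    Expected columns: ``id`` and ``qC_e``, plus either orbital energies
    (``e_homo_eV``, ``e_lumo_eV``) or a direct electron affinity
    (``EA_eV``).  When orbital energies are present the conceptual-DFT
    quantities are derived; a supplied ``EA_eV`` is taken verbatim.
    Duplicate ids are rejected.
    """
    conv = conv or Conventions()
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'id'")
    if "qC_e" not in df.columns:
        raise ValueError(f"{path}: missing required column 'qC_e'")
    has_orbitals = {"e_homo_eV", "e_lumo_eV"}.issubset(df.columns)
    if not has_orbitals and "EA_eV" not in df.columns:
        raise ValueError(
            f"{path}: need either columns (e_homo_eV, e_lumo_eV) or EA_eV"
        )
    dupes = df["id"].astype(str)[df["id"].astype(str).duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate ids: {sorted(set(dupes))}")

    out = pd.DataFrame({"id": df["id"].astype(str), "qC": df["qC_e"].astype(float)})
    if has_orbitals:
        recs = [conceptual_dft(h, l, conv)
                for h, l in zip(df["e_homo_eV"].astype(float),
                                df["e_lumo_eV"].astype(float))]
        out["e_homo"] = [r.e_homo for r in recs]
        out["e_lumo"] = [r.e_lumo for r in recs]
        out["I"] = [r.I for r in recs]
        out["EA"] = [r.A for r in recs]
        out["mu"] = [r.mu for r in recs]
        out["eta"] = [r.eta for r in recs]
        out["omega"] = [r.omega for r in recs]
        out["gap"] = [r.gap for r in recs]
    if "EA_eV" in df.columns:
        ea = df["EA_eV"].astype(float)
        if "EA" in out.columns:
            out["EA"] = out["EA"].where(ea.isna(), ea)
        else:
            out["EA"] = ea
    return out
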
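"""Convention flags for descriptor and electronic-index computation.

Several descriptor families (GETAWAY autocorrelations, spectral geometry
indices, the Unsat unsaturation count, conceptual-DFT hardness) admit more
than one convention in the literature and in descriptor software.  The
choices below are the package defaults; every one can be overridden through
a :class:`Conventions` instance or a ``key = value`` config file.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class Conventions:
    """Tunable convention flags.

    unsat_literal
        The printed unsaturation formula contains the term ``(nAB + 1)/2``,
        which is 0.5 even for molecules with no aromatic bonds.  By default
        that term is taken as 0 when ``nAB == 0`` (a saturated molecule has
        zero unsaturation); setting this flag restores the literal formula.
    getaway_include_h
        Include hydrogens in the GETAWAY molecular-influence matrix and in
        the topological distances used for the lag-4 autocorrelation.
        Default is heavy atoms only.
    sppos_include_h
        Include hydrogens in the reciprocal-squared geometry matrix of
        SpPosA_RG.  Default heavy atoms only; the normalisation divisor is
        the size of the chosen atom set.
    hardness_factor
        ``"half"`` uses eta = (I - A)/2 (and mu = -(I + A)/2); ``"full"``
        uses eta = I - A.  Both appear in the conceptual-DFT literature.
    corr_threshold
        Pairwise |Pearson r| above which one of two descriptors is dropped
        during pre-filtering.
    test_fraction
        Fraction of compounds held out as the external test set.
    """

    unsat_literal: bool = False
    getaway_include_h: bool = False
    sppos_include_h: bool = False
    hardness_factor: str = "half"
    corr_threshold: float = 0.90
    test_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.hardness_factor not in ("half", "full"):
            raise ValueError(
                f"hardness_factor must be 'half' or 'full', got {self.hardness_factor!r}"
            )
        if not 0.0 < self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must be in (0, 1]")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


def load_config(path: str | Path) -> Conventions:
    """Read a ``key = value`` config file into a :class:`Conventions`.

    Lines starting with ``#`` and blank lines are ignored.  Unknown keys
    raise ``ValueError``.
    """
    known = {f.name: f.type for f in fields(Conventions)}
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in ("unsat_literal", "getaway_include_h", "sppos_include_h"):
            kwargs[key] = value.lower() in ("1", "true", "yes", "on")
        elif key in ("corr_threshold", "test_fraction"):
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return Conventions(**kwargs)
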
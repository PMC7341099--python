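"""Embedded loop-additive energy model.

The free energy of a secondary structure is the sum of the energies of its
loops; each base pair closes exactly one loop and contributes a per-pair
stabilization to that loop, on top of a class/size-dependent penalty:

* stack (size 0, one immediately interior pair): stacking bonus
* hairpin / bulge / interior: tabulated size penalty with a logarithmic
  extrapolation beyond the table
* multiloop: affine in the number of branches and unpaired bases
* exterior loop: zero

Values are in kcal/mol at 37 degrees C.  They are deliberately simple,
documented numbers rather than a full thermodynamic table: the package is
self-contained and every fold is verifiable against exhaustive enumeration
under the identical model.  An external thermodynamic folder can be plugged
in through :func:`loopscreen.fold.fold_mfe`'s ``folder`` hook.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

GAS_CONSTANT = 1.987e-3  # kcal / (mol K)
TEMPERATURE = 310.15  # K (37 C)
RT = GAS_CONSTANT * TEMPERATURE


@dataclass(frozen=True)
class EnergyModel:
    """Parameter set for the loop-additive model (kcal/mol)."""

    pair_energy: dict = field(
        default_factory=lambda: {
            ("G", "C"): -3.0,
            ("C", "G"): -3.0,
            ("A", "U"): -2.0,
            ("U", "A"): -2.0,
            ("G", "U"): -1.0,
            ("U", "G"): -1.0,
        }
    )
    stack_bonus: float = -0.5
    hairpin_table: dict = field(
        default_factory=lambda: {3: 1.5, 4: 1.7, 5: 1.8, 6: 2.0}
    )
    bulge_table: dict = field(default_factory=lambda: {1: 1.0, 2: 1.4, 3: 1.8})
    interior_table: dict = field(default_factory=lambda: {2: 1.0, 3: 1.3, 4: 1.6})
    loop_extrapolation: float = 0.3  # prefactor of the log size extrapolation
    ml_close: float = 2.0
    ml_branch: float = 0.3
    ml_unpaired: float = 0.1
    # intermolecular duplex terms
    duplex_init: float = 4.1
    position_penalty: float = 0.0  # per-pair linear position weight
    dangle_energy: float = -0.3  # per available flank base (Eq.-1 dangles)
    temperature: float = TEMPERATURE

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * self.temperature

    def pair(self, a: str, b: str) -> float:
        return self.pair_energy[(a, b)]

    def _sized(self, table: dict, n: int) -> float:
        if n in table:
            return table[n]
        nmax = max(table)
        return table[nmax] + self.loop_extrapolation * math.log(n / nmax)

    def hairpin(self, n: int) -> float:
        if n < 3:
            raise ValueError("hairpin loops have at least 3 unpaired bases")
        return self._sized(self.hairpin_table, n)

    def bulge(self, n: int) -> float:
        if n < 1:
            raise ValueError("bulge size must be >= 1")
        return self._sized(self.bulge_table, n)

    def interior(self, n: int) -> float:
        if n < 2:
            raise ValueError("interior loops have >= 2 unpaired bases")
        return self._sized(self.interior_table, n)

    def multiloop(self, n_branches: int, n_unpaired: int) -> float:
        return self.ml_close + self.ml_branch * n_branches + self.ml_unpaired * n_unpaired

    def two_loop(self, i: int, j: int, k: int, l: int) -> float:
        """Penalty of the loop closed by (i,j) with (k,l) immediately interior."""
        u1, u2 = k - i - 1, j - l - 1
        if u1 == 0 and u2 == 0:
            return self.stack_bonus
        if u1 == 0 or u2 == 0:
            return self.bulge(u1 + u2)
        return self.interior(u1 + u2)


DEFAULT_MODEL = EnergyModel()
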
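"""Physical constants used across the package.

The two ratios named ``gamma`` in the hydration literature are deliberately
kept apart here: :data:`PROTON_GYROMAGNETIC_RATIO` is the magnetic-resonance
gyromagnetic ratio (rad s^-1 T^-1), while the ``GAMMA_*`` constants are
proton-density ratios of candidate water-soluble solids expressed in units
of the proton density of water.  They must never share an identifier.
"""

from __future__ import annotations

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
PROTON_GYROMAGNETIC_RATIO: float = 2.6752218744e8

#: Proton-density ratio (solute/water) averaged over common carbohydrates.
GAMMA_SUGARS: float = 0.598

#: Proton-density ratio (solute/water) averaged over common polyols.
GAMMA_POLYOLS: float = 0.715

#: Mean of the sugar and polyol values; default when the solute is unknown.
GAMMA_MIXED: float = 0.657

assert GAMMA_SUGARS < GAMMA_MIXED < GAMMA_POLYOLS
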
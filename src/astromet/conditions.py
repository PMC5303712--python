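"""Reference exchange conditions for the astrocyte analysis.

The packaged ``normal_physiological.tsv`` carries the literature uptake and
release rates for astrocytes in the glutamatergic excitatory state (glucose
0.16, O2 up to 0.530, glutamate 0.232 μmol/g tissue/min, ...).  Two glucose
figures coexist in the source literature: a directly measured astrocyte
uptake of 0.16 and the half-share of the whole-brain excitatory intake,
0.980 / 2 = 0.490 μmol/g/min.  The flux analyses in this package use the
half-share figure (it is the one consistent with the hexokinase flux the
analysis reproduces); :func:`excitatory_condition` applies it on top of the
packaged table.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

from .simulation import Condition

#: whole-brain glucose intake during glutamatergic excitation, μmol/g/min
BRAIN_GLUCOSE_INTAKE = 0.980
#: astrocyte share: half of the brain intake
ASTROCYTE_GLUCOSE_UPTAKE = BRAIN_GLUCOSE_INTAKE / 2.0
#: basal hypoxanthine turnover available to xanthine oxidase, μmol/g/min
BASAL_HYPOXANTHINE = 0.005


def normal_physiological_condition() -> Condition:
    """The packaged literature constraint table, verbatim."""
    from .io import read_condition  # deferred: io imports Condition from simulation

    with resources.as_file(
        resources.files("astromet.data") / "normal_physiological.tsv"
    ) as path:
        cond = read_condition(path)
    cond.name = "normal_physiological"
    return cond


def excitatory_condition(
    glucose_uptake: float = ASTROCYTE_GLUCOSE_UPTAKE,
    hypoxanthine: Optional[float] = BASAL_HYPOXANTHINE,
) -> Condition:
    """Normal physiological condition with the half-brain-share glucose rate.

    This is the constraint set under which the flux analyses are run:
    glucose uptake capacity 0.490, O2 0.530, glutamate 0.232 μmol/g/min and
    the remaining packaged rates.  ``hypoxanthine`` sets the basal purine
    turnover available to the ROS branch (None leaves it closed).
    """
    cond = normal_physiological_condition().copy(name="excitatory")
    cond.set_uptake("EX_glc", glucose_uptake)
    if hypoxanthine is not None:
        cond.set_uptake("EX_hxan", hypoxanthine)
    return cond
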
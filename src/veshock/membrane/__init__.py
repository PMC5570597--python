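from .base import MembraneParams, validate_state
from .tp06 import TP06Model
from .tt04 import TT04Model
from .reduced import PassiveMembrane, ReducedExcitable
from .singlecell import (equilibrate, run_single_cell, paced_checkpoints,
                         apd90, SingleCellTrace)

#: registry of selectable membrane models
MODELS = {
    "human_ventricular_2004": TT04Model,
    "human_ventricular_2006": TP06Model,
    "reduced_test": ReducedExcitable,
    "passive": PassiveMembrane,
}


def make_model(name: str = "human_ventricular_2004", **kwargs):
    """Instantiate a membrane model by registry name.

    The 2004 epicardial human ventricular model is the study default: its
    late-phase-3 repolarisation at a 500 ms cycle length best matches the
    refractoriness landscape the shock protocols are defined on.
    """
    try:
        cls = MODELS[name]
    except KeyError:
        raise ValueError(f"unknown membrane model {name!r}; "
                         f"choose from {sorted(MODELS)}") from None
    return cls(**kwargs)


__all__ = [
    "MembraneParams", "validate_state", "TP06Model", "TT04Model",
    "PassiveMembrane", "ReducedExcitable", "equilibrate", "run_single_cell",
    "paced_checkpoints", "apd90", "SingleCellTrace", "MODELS", "make_model",
]
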
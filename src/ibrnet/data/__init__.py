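"""Packaged network fixtures.

The mammalian cell-cycle Boolean network (10 genes: CycD, Rb, p27, E2F,
CycE, CycA, Cdc20, Cdh1, UbcH10, CycB) ships in two variants: the wild-type
wiring, with the extracellular CycD input held at 0, and the cancerous
p27-mutant in which p27 is shut down (its update rule is the constant 0).
"""

from importlib import resources
import json

from ..network import BooleanNetwork

_FILES = {
    "wild-type": "cellcycle_wildtype.json",
    "p27-mutant": "cellcycle_p27mut.json",
}


def load_cell_cycle(variant: str = "wild-type") -> BooleanNetwork:
    """Load one packaged cell-cycle network variant."""
    try:
        fname = _FILES[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(_FILES)}") from None
    text = resources.files(__package__).joinpath(fname).read_text()
    return BooleanNetwork.from_dict(json.loads(text))
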
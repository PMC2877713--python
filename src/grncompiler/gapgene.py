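"""The Drosophila gap-gene cross-regulation model.

Network: BCD activates hb and kni; HB and KNI mutually repress; TLL
represses kni.  Compiled with one binding site per regulator this gives

* hb operon (activator BCD, repressor KNI): 4 occupancy states,
* kni operon (activator BCD, repressors HB and TLL): 8 occupancy states,
* the proteins HB and KNI,

i.e. a 14-dimensional state per spatial position, with one gene-total
conservation law per gene.  BCD and TLL are maternal inputs held constant
in time with non-homogeneous anterior-posterior profiles; maternal hb
transcript is folded into the initial HB protein profile.  Predicted
profiles are read out at a finite integration time T (itself a free
parameter of the calibration) — they are out-of-equilibrium patterns, not
steady states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .graph_model import DoubleGraph, gapgene_graph
from .mass_action import ODESystem, build_odes, conservation_laws
from .regulation_compiler import ReactionNetwork, compile_reactions
from .spatial import SpatialField, SpatialProfile, simulate_field

__all__ = ["GapGeneModel", "build_gapgene_model", "predict_profiles",
           "DEFAULT_GENE_TOTALS"]

#: total operon concentration per gene (arbitrary units, fit parameters)
DEFAULT_GENE_TOTALS = {"HB": 1.0, "KNI": 1.0}

EXPECTED_STATE_DIM = 14


@dataclass
class GapGeneModel:
    graph: DoubleGraph
    network: ReactionNetwork
    odesys: ODESystem
    gene_totals: dict[str, float]

    @property
    def state_species(self) -> list[str]:
        return self.odesys.state_species

    @property
    def free_state_names(self) -> dict[str, str]:
        """gene protein name -> name of its fully-free operon species."""
        return {"HB": "HB_a0_r0", "KNI": "KNI_a0_r00"}

    def parameter_names(self) -> list[str]:
        return list(self.network.parameters)


def build_gapgene_model(
    parameters: Mapping[str, float] | None = None,
    gene_totals: Mapping[str, float] | None = None,
) -> GapGeneModel:
    """Compile the gap-gene network into its 14-equation ODE system.

    ``parameters`` overrides individual rate constants by name;
    ``gene_totals`` sets the conserved total operon concentration per gene
    (keys ``HB``, ``KNI``).  All rates must be positive.  An internal
    trip-wire asserts the expected state dimension and the two gene-total
    conservation laws.
    """
    totals = dict(DEFAULT_GENE_TOTALS)
    if gene_totals:
        totals.update(gene_totals)
    if any(v <= 0 for v in totals.values()):
        raise ValueError("gene totals must be positive")
    graph = gapgene_graph()
    network = compile_reactions(graph, semantics="per_site")
    if parameters:
        if any(v <= 0 for v in parameters.values()):
            raise ValueError("all rate parameters must be positive")
        network = network.with_parameters(parameters)
    # constant inputs get placeholder values; spatial runs override per
    # position
    network.initial_conditions.setdefault("BCD", 0.0)
    network.initial_conditions.setdefault("TLL", 0.0)
    odesys = build_odes(network)

    if odesys.n_state != EXPECTED_STATE_DIM:
        raise RuntimeError(
            f"gap-gene model compiled to {odesys.n_state} state equations, "
            f"expected {EXPECTED_STATE_DIM}"
        )
    laws = conservation_laws(odesys)
    if len(laws) != 2:
        raise RuntimeError(
            f"gap-gene model has {len(laws)} conservation laws, expected 2 "
            "(one gene total per gene)"
        )
    return GapGeneModel(graph, network, odesys, totals)


def predict_profiles(
    model: GapGeneModel,
    input_field: SpatialField,
    T: float,
    maternal_hb: SpatialProfile | None = None,
    method: str = "batch_rk4",
    n_steps: int = 600,
) -> SpatialField:
    """Integrate the model at every position from cycle-13-like initial data.

    Initial conditions per position: HB at the maternal profile (taken from
    ``input_field['HB_maternal']`` unless given explicitly), KNI at 0, and
    each operon entirely in its free state at the gene-total concentration.
    BCD and TLL are read from ``input_field`` and held constant.  Returns
    all state profiles at time ``T`` (out-of-equilibrium readout).
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    if maternal_hb is None:
        if "HB_maternal" not in input_field:
            raise KeyError("provide maternal_hb or an 'HB_maternal' profile")
        maternal_hb = input_field["HB_maternal"]
    inputs = SpatialField({
        "BCD": input_field["BCD"], "TLL": input_field["TLL"]
    })
    if T == 0:
        pos = inputs.positions
        zeros = np.zeros(len(pos))
        out = {}
        for s in model.state_species:
            if s == "HB":
                out[s] = SpatialProfile(pos, maternal_hb.values.copy())
            elif s == model.free_state_names["HB"]:
                out[s] = SpatialProfile(pos, np.full(len(pos), model.gene_totals["HB"]))
            elif s == model.free_state_names["KNI"]:
                out[s] = SpatialProfile(pos, np.full(len(pos), model.gene_totals["KNI"]))
            else:
                out[s] = SpatialProfile(pos, zeros.copy())
        return SpatialField(out)
    gene_totals = {
        model.free_state_names["HB"]: model.gene_totals["HB"],
        model.free_state_names["KNI"]: model.gene_totals["KNI"],
    }
    return simulate_field(
        model.network,
        inputs,
        gene_totals,
        t_final=T,
        initial_proteins=SpatialField({"HB": maternal_hb}),
        method=method,
        n_steps=n_steps,
    )
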
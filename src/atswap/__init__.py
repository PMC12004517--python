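"""atswap: relative binding free energies by alchemical transfer with
coordinate swapping, on desk-scale systems with known answers."""

from importlib import resources as _resources

from .alchemy import (
    alchemical_potential,
    default_schedule,
    lambda_params,
    softcore,
    softplus_w,
)
from .estimators import (
    bar,
    bootstrap_sigma,
    discard_equilibration,
    exp_estimator,
    uwham,
)
from .model import (
    KB,
    AlchemicalPartition,
    Atom,
    FormatError,
    FreeEnergyNetwork,
    LambdaState,
    SampleSet,
    SoftcoreParams,
    Structure,
    ValidationError,
)
from .network import cycle_closure, enumerate_cycles, hysteresis, network_summary
from .pipeline import RBFEResult, estimate, make_system, toy_rbfe
from .restraints import RestraintSet, flat_bottom
from .sampling import ReplicaState, System, attempt_exchange, metropolis_step, run_hrex
from .synthetic import (
    analytic_rbfe,
    make_network_fixture,
    make_selftransform_pair,
    make_toy_pair,
)
from .toyff import Bond, EnergyModel, SwitchableWell, bond_energy, lj_energy
from .transform import (
    Displacement,
    atm_transform,
    ats_transform,
    displacement_vector,
    perturbation_energy,
)

__version__ = "0.1.0"


def packaged_data(name: str):
    """Path to a packaged data file (e.g. the TIAM-1 PDZ edge list
    ``tiam1_pdz_edges.tsv`` or the default schedule ``schedule_22.tsv``)."""
    return _resources.files("atswap.data").joinpath(name)
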
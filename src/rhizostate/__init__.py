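"""Bayesian state-space modelling of fine root production.

A latent mass-balance model of standing fine-root area whose growth rate
responds to soil temperature and moisture through time-varying coefficients,
observed through a hierarchical gamma error model across scanners and images.
"""

from .core import (
    EnvForcingSeries,
    ProductionObservations,
    ScalarParams,
    LatentTrajectory,
    DispersionParams,
    PriorConfig,
    PositivityError,
)

__version__ = "0.1.0"
__all__ = [
    "EnvForcingSeries", "ProductionObservations", "ScalarParams",
    "LatentTrajectory", "DispersionParams", "PriorConfig", "PositivityError",
    "FineRootModel", "FineRootResults", "MCMCConfig",
]


def __getattr__(name):
    # late imports keep `import rhizostate` light
    if name in ("FineRootModel", "FineRootResults"):
        from . import model
        return getattr(model, name)
    if name == "MCMCConfig":
        from .inference import MCMCConfig
        return MCMCConfig
    raise AttributeError(name)
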
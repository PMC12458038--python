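"""Built-in experiment designs: the six receptor-ligand conditions.

Each design pairs one nanopore variant (receptor outside the lumen, NP-O,
or 25 nm inside the confining 7.5 nm lumen, NP-I) with one ligand (a 20-nt
ssDNA, an anti-biotin antibody, or streptavidin) and carries the published
concentration series, sampling protocol and generating kinetic constants of
that condition. The constants table mirrors the published affinity table,
including which cell of each row was measured and which was closed through
K_d = k_off / k_on (association for the antibody rows is too fast to
time-resolve; dissociation for the DNA rows comes from the closure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExperimentDesign", "AFFINITY_TABLE", "builtin_designs", "get_design"]

NM = 1e-9
MIN = 60.0

#: published kinetic constants (value, error) per condition; provenance
#: "fitted" = measured directly, "derived-via-closure" = closed from the others.
AFFINITY_TABLE: dict[str, dict] = {
    "NP-O^DNA": {
        "ligand": "L^DNA",
        "Kd": (1.4e-9, 0.6e-9),
        "k_on": (2.7e5, 0.3e5),
        "k_off": (3.9e-4, 1.7e-4),
        "provenance": {"Kd": "fitted", "k_on": "fitted", "k_off": "derived-via-closure"},
    },
    "NP-I^DNA": {
        "ligand": "L^DNA",
        "Kd": (1.5e-9, 0.4e-9),
        "k_on": (1.0e5, 0.3e5),
        "k_off": (1.5e-4, 0.6e-4),
        "provenance": {"Kd": "fitted", "k_on": "fitted", "k_off": "derived-via-closure"},
    },
    "NP-O^Biot": {
        "ligand": "L^Ab",
        "Kd": (3.4e-8, 0.9e-8),
        "k_on": (3.3e5, 1.1e5),
        "k_off": (1.1e-2, 0.2e-2),
        "provenance": {"Kd": "fitted", "k_on": "derived-via-closure", "k_off": "fitted"},
    },
    "NP-I^Biot": {
        "ligand": "L^Ab",
        "Kd": (3.2e-8, 1.1e-8),
        "k_on": (1.7e5, 0.6e5),
        "k_off": (0.54e-2, 0.06e-2),
        "provenance": {"Kd": "fitted", "k_on": "derived-via-closure", "k_off": "fitted"},
    },
    "NP-O^Strep": {
        "ligand": "L^Strep",
        "Kd": (2e-12, 30e-12),
        "k_on": (1.2e6, 0.1e6),
        "k_off": None,  # not reported; implied by closure
        "provenance": {"Kd": "fitted", "k_on": "fitted", "k_off": "not-reported"},
    },
    "NP-I^Strep": {
        "ligand": "L^Strep",
        "Kd": (4e-12, 25e-12),
        "k_on": (1.0e6, 0.2e6),
        "k_off": None,
        "provenance": {"Kd": "fitted", "k_on": "fitted", "k_off": "not-reported"},
    },
}

#: reported fold changes between nonconfined and confined DNA kinetics
FOLD_CHANGES = {"k_on_dna": 2.7, "k_off_dna": 2.6}


@dataclass(frozen=True)
class ExperimentDesign:
    """One synthetic experiment: concentrations, protocol, generating constants."""

    name: str
    pore: str
    ligand: str
    ligand_concs: tuple[float, ...]  # M
    pore_conc: float  # M
    k_on: float  # M^-1 s^-1, generating
    k_off: float  # s^-1, generating
    Kd: float  # M, generating (= k_off / k_on)
    sampling_times: tuple[float, ...] = ()  # s; empty if kinetics unresolvable
    equilibration_time: float = 180 * MIN
    isotherm: str = "hyperbolic"  # or "depletion"
    displacement: dict | None = None  # {"labeled_M":..., "competitor_M":..., "times":...}
    ccp_noise_sd: float = 2.0  # CCP percentage points
    amplitude: float = 60.0  # plateau A = 100 * f_ov

    def __post_init__(self):
        if any(c <= 0 for c in self.ligand_concs) or self.pore_conc <= 0:
            raise ValueError("concentrations must be > 0")
        if self.sampling_times and any(np.diff(self.sampling_times) <= 0):
            raise ValueError("sampling times must be increasing")


def _times(stop_min: float, step_min: float) -> tuple[float, ...]:
    return tuple(np.arange(0.0, stop_min * MIN + 1e-9, step_min * MIN))


def builtin_designs() -> dict[str, ExperimentDesign]:
    """Catalog of the six published conditions plus displacement protocols."""
    t_3h = _times(180, 5)
    designs = {}
    designs["NP-O^DNA"] = ExperimentDesign(
        "NP-O^DNA", "NP-O^DNA", "L^DNA",
        tuple(c * NM for c in (0.7, 1.2, 1.4, 1.6, 1.9, 2.7, 6.4)),
        1.3 * NM, AFFINITY_TABLE["NP-O^DNA"]["k_on"][0], AFFINITY_TABLE["NP-O^DNA"]["k_off"][0],
        AFFINITY_TABLE["NP-O^DNA"]["Kd"][0], sampling_times=t_3h,
    )
    designs["NP-I^DNA"] = ExperimentDesign(
        "NP-I^DNA", "NP-I^DNA", "L^DNA",
        tuple(c * NM for c in (0.8, 1.0, 1.7, 2.4, 3.1, 5.0)),
        1.3 * NM, AFFINITY_TABLE["NP-I^DNA"]["k_on"][0], AFFINITY_TABLE["NP-I^DNA"]["k_off"][0],
        AFFINITY_TABLE["NP-I^DNA"]["Kd"][0], sampling_times=t_3h,
    )
    # antibody binding equilibrates within minutes (too fast to time-resolve):
    # equilibrium titrations only, k_off from competition displacement.
    ab_concs_o = tuple(np.geomspace(1.1, 140.0, 8) * NM)
    ab_concs_i = tuple(np.geomspace(1.1, 150.0, 8) * NM)
    designs["NP-O^Biot"] = ExperimentDesign(
        "NP-O^Biot", "NP-O^Biot", "L^Ab", ab_concs_o, 1.3 * NM,
        AFFINITY_TABLE["NP-O^Biot"]["k_on"][0], AFFINITY_TABLE["NP-O^Biot"]["k_off"][0],
        AFFINITY_TABLE["NP-O^Biot"]["Kd"][0],
        displacement={
            "labeled_M": 250 * NM, "competitor_M": 1000 * NM,
            "times": _times(10, 1.0 / 6.0),  # 0-600 s every 10 s
        },
    )
    designs["NP-I^Biot"] = ExperimentDesign(
        "NP-I^Biot", "NP-I^Biot", "L^Ab", ab_concs_i, 1.3 * NM,
        AFFINITY_TABLE["NP-I^Biot"]["k_on"][0], AFFINITY_TABLE["NP-I^Biot"]["k_off"][0],
        AFFINITY_TABLE["NP-I^Biot"]["Kd"][0],
        displacement={
            "labeled_M": 30 * NM, "competitor_M": 1000 * NM,
            "times": _times(15, 0.25),  # 0-900 s every 15 s
        },
    )
    designs["NP-O^Strep"] = ExperimentDesign(
        "NP-O^Strep", "NP-O^Biot", "L^Strep",
        tuple(c * NM for c in (0.6, 0.9, 1.3, 1.5, 1.5, 2.3)),
        1.3 * NM, AFFINITY_TABLE["NP-O^Strep"]["k_on"][0],
        AFFINITY_TABLE["NP-O^Strep"]["Kd"][0] * AFFINITY_TABLE["NP-O^Strep"]["k_on"][0],
        AFFINITY_TABLE["NP-O^Strep"]["Kd"][0], sampling_times=t_3h, isotherm="depletion",
    )
    designs["NP-I^Strep"] = ExperimentDesign(
        "NP-I^Strep", "NP-I^Biot", "L^Strep",
        tuple(c * NM for c in (0.6, 0.7, 0.8, 1.2, 1.4, 1.8, 2.7)),
        1.3 * NM, AFFINITY_TABLE["NP-I^Strep"]["k_on"][0],
        AFFINITY_TABLE["NP-I^Strep"]["Kd"][0] * AFFINITY_TABLE["NP-I^Strep"]["k_on"][0],
        AFFINITY_TABLE["NP-I^Strep"]["Kd"][0], sampling_times=t_3h, isotherm="depletion",
    )
    return designs


def get_design(name: str) -> ExperimentDesign:
    """Look up a built-in design; unknown names list what is available.

    ``"<pore> displacement"`` returns the pore's design restricted to its
    displacement protocol.
    """
    designs = builtin_designs()
    base = name.removesuffix(" displacement").strip()
    if base not in designs:
        raise KeyError(
            f"unknown design {name!r}; available: {sorted(designs)} "
            "(append ' displacement' for the competition protocols)"
        )
    design = designs[base]
    if name.endswith("displacement") and design.displacement is None:
        raise KeyError(f"design {base!r} has no displacement protocol")
    return design
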
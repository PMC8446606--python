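import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from longgblup import (
    BSplineBasis,
    GenotypePanel,
    simulate_phenotypes,
    simulate_ril_genotypes,
    qc_filter,
    vanraden_grm,
)
from longgblup.residuals import ResidualClassMap

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


class ConstantBasis:
    """Single-coefficient basis (phi_0 = 1): the random intercept model.

    Used as the m = 1 limit for closed-form BLUP and brute-force REML
    oracles; mirrors the basis interface.
    """

    kind = "constant"

    def __init__(self, dap_min=27, dap_max=83):
        self.dap_min = dap_min
        self.dap_max = dap_max

    @property
    def n_coef(self):
        return 1

    def design_matrix(self, daps):
        return np.ones((np.atleast_1d(daps).size, 1))

    transform = design_matrix

    def to_config(self):
        return {"kind": "constant", "dap_min": self.dap_min, "dap_max": self.dap_max}


@pytest.fixture
def const_basis():
    return ConstantBasis()


@pytest.fixture(scope="session")
def small_panel():
    """A small but realistic RIL panel reused across tests (read-only)."""
    rng = np.random.default_rng(42)
    return simulate_ril_genotypes(
        n_families=12, lines_per_family=6, n_snps=300, n_chrom=5, rng=rng
    )


@pytest.fixture(scope="session")
def small_grm(small_panel):
    return vanraden_grm(qc_filter(small_panel))


@pytest.fixture(scope="session")
def small_dataset(small_panel):
    """Panel + phenotypes simulated from a linear B-spline model."""
    rng = np.random.default_rng(43)
    basis = BSplineBasis(degree=1, knots=(44, 66), dap_min=27, dap_max=83)
    grid = np.arange(27, 84, 4)
    rmap = ResidualClassMap.homogeneous(27, 83)
    phen, truth = simulate_phenotypes(
        small_panel, basis, residual_map=rmap, dap_grid=grid,
        env_reps=["E1", "E2"], rng=rng,
    )
    return {"panel": small_panel, "basis": basis, "grid": grid,
            "rmap": rmap, "phen": phen, "truth": truth}


def toy_panel(dosages, chrom=None, pos=None):
    """Build a GenotypePanel from a raw dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, s = dosages.shape
    return GenotypePanel(
        line_ids=[f"L{i}" for i in range(n)],
        dosages=dosages,
        snp_ids=[f"s{j}" for j in range(s)],
        chrom=np.array(chrom if chrom is not None else ["1"] * s, dtype=object),
        pos_bp=np.array(pos if pos is not None else np.arange(1, s + 1) * 100),
    )
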
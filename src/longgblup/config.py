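"""Run configuration shared by the CLI and the pipeline driver."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .basis import BSplineBasis, LegendreBasis
from .residuals import ResidualClassMap


@dataclass
class RunConfig:
    """Everything a pipeline run needs, validated up front.

    All randomness in a run flows from ``seed`` through named per-stage
    generators, so identical configs give byte-identical outputs.
    """

    basis_kind: str = "bspline"            # "legendre" | "bspline"
    order: int = 3                          # Legendre highest order
    degree: int = 1                         # B-spline degree (1 or 2)
    knots: tuple = (44, 66)                 # B-spline interior knots
    residual_mode: str = "heterogeneous"    # "homogeneous" | "heterogeneous"
    residual_intervals: tuple | None = None  # closed [start, end] intervals
    dap_min: int = 27
    dap_max: int = 83
    cv_folds: int = 5
    top_k: int = 10
    window_half_width: int = 25_000
    seed: int = 0
    reestimate_varcomps: bool = True
    max_iter: int = 100
    tol: float = 1e-6
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.basis_kind not in ("legendre", "bspline"):
            raise ValueError(f"unknown basis kind: {self.basis_kind!r}")
        if self.dap_min >= self.dap_max:
            raise ValueError("dap_min must be < dap_max")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        kn = sorted(self.knots)
        if list(kn) != list(self.knots):
            raise ValueError("knots must be strictly increasing")
        if self.basis_kind == "bspline":
            for k in self.knots:
                if not self.dap_min < k < self.dap_max:
                    raise ValueError(
                        f"knot {k} must lie strictly inside ({self.dap_min}, {self.dap_max})"
                    )
        if self.residual_intervals is not None:
            m = ResidualClassMap(tuple(tuple(p) for p in self.residual_intervals))
            if (m.dap_min, m.dap_max) != (self.dap_min, self.dap_max):
                raise ValueError("residual intervals must partition the DAP range")

    def basis(self):
        if self.basis_kind == "legendre":
            return LegendreBasis(order=self.order, dap_min=self.dap_min, dap_max=self.dap_max)
        return BSplineBasis(
            degree=self.degree, knots=self.knots,
            dap_min=self.dap_min, dap_max=self.dap_max,
        )

    def residual_map(self) -> ResidualClassMap | None:
        if self.residual_mode == "homogeneous":
            return ResidualClassMap.homogeneous(self.dap_min, self.dap_max)
        if self.residual_intervals is not None:
            return ResidualClassMap(tuple(tuple(p) for p in self.residual_intervals))
        default = ResidualClassMap.default()
        if (self.dap_min, self.dap_max) == (default.dap_min, default.dap_max):
            return default
        return ResidualClassMap.homogeneous(self.dap_min, self.dap_max)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["knots"] = list(self.knots)
        if d["residual_intervals"] is not None:
            d["residual_intervals"] = [list(p) for p in d["residual_intervals"]]
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "knots" in d:
            d["knots"] = tuple(d["knots"])
        if d.get("residual_intervals") is not None:
            d["residual_intervals"] = tuple(tuple(p) for p in d["residual_intervals"])
        return cls(**d)
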
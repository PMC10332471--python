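"""Run configuration shared by the CLI subcommands.

A ``RunConfig`` aggregates every tunable of the pipeline and round-trips
losslessly through a flat ``key=value`` text file, so any run can be
reproduced from its emitted config record.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, fields

from .decomposition import SvtParams
from .masking import DEFAULT_S_HARD, DEFAULT_SE_SIZE, DEFAULT_V_HARD
from .metrics import DEFAULT_COV_MARGIN

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    s_hard: float = DEFAULT_S_HARD
    v_hard: float = DEFAULT_V_HARD
    se_size: int = DEFAULT_SE_SIZE
    mu0: float = 0.0006
    lam: float = 1.2
    zeta_rel: float = 1e-4
    max_iter: int = 100
    cov_margin: int = DEFAULT_COV_MARGIN
    output_dir: str = "."
    emit_mask: bool = False
    emit_highlight: bool = False
    emit_metrics: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_hard <= 1.0 or not 0.0 <= self.v_hard <= 1.0:
            raise ValueError("s_hard and v_hard must lie in [0, 1]")
        if self.se_size < 1 or self.se_size % 2 == 0:
            raise ValueError("se_size must be a positive odd integer")
        if self.cov_margin < 0:
            raise ValueError("cov_margin must be nonnegative")
        # delegate schedule validation
        self.svt_params()

    def svt_params(self) -> SvtParams:
        return SvtParams(
            mu0=self.mu0, lam=self.lam, zeta_rel=self.zeta_rel, max_iter=self.max_iter
        )

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for key, value in sorted(asdict(self).items()):
                fh.write(f"{key}={value!r}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        import ast

        types = {f.name: f for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, _, raw = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                kwargs[key] = ast.literal_eval(raw.strip())
        return cls(**kwargs)
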
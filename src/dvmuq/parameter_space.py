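"""The 13-parameter uniform space of the vegetation model and its Latin hypercube samples.

The sampled parameters control light extinction (k_beer), photosynthesis
(theta, alpha_a, alpha_C3), mortality (k_mort1, k_mort2), tree allometry
(k_allom1, k_allom3, k_rp, k_la_sa, CA_max), respiration (r_growth) and
sapling establishment (est_max).  Each parameter is treated as uniformly
distributed on a published range, sampled independently (parameter
correlations are deliberately neglected).

Latin hypercube sampling follows the classic three-step stratified scheme:
each parameter's range is split into ``n`` equal-probability strata, one
value is drawn uniformly inside each stratum, and the per-parameter draws
are combined by independent random permutations into ``n`` joint
realizations.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical parameter order used everywhere in the package.
PARAMETER_ORDER = (
    "k_beer",
    "theta",
    "k_mort1",
    "k_mort2",
    "alpha_a",
    "alpha_C3",
    "k_allom1",
    "k_allom3",
    "k_rp",
    "k_la_sa",
    "CA_max",
    "r_growth",
    "est_max",
)

#: Replacement range for the degenerate printed k_mort1 range [0.01, 0.01].
#: The repaired default brackets the standard value 0.05.
K_MORT1_REPAIRED_RANGE = (0.01, 0.1)


class InvalidSpecError(ValueError):
    """A parameter specification is unusable (e.g. degenerate range)."""


@dataclass(frozen=True)
class ParameterSpec:
    """One sampled model parameter: default value and uniform range."""

    name: str
    standard: float
    lower: float
    upper: float
    description: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise InvalidSpecError(
                f"parameter {self.name!r}: lower bound {self.lower} must be "
                f"strictly below upper bound {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class SampleMatrix:
    """An n-by-k Latin hypercube realization of the parameter space."""

    values: np.ndarray
    param_names: tuple[str, ...]
    seed: int
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "param_names", tuple(self.param_names))
        if values.ndim != 2 or values.shape[1] != len(self.param_names):
            raise ValueError("values must be n_samples x n_params")
        if self.sample_ids is None:
            object.__setattr__(
                self, "sample_ids", np.arange(1, values.shape[0] + 1)
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.param_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=list(self.param_names), index=self.sample_ids
        )

    def row_dict(self, i: int) -> dict[str, float]:
        """Parameter values of sample ``i`` (0-based) as a mapping."""
        return dict(zip(self.param_names, self.values[i]))


@dataclass(frozen=True)
class StratificationReport:
    """Per-column occupancy check of the equal-width strata."""

    passed: bool
    column_pass: dict[str, bool]
    offending_strata: dict[str, list[int]]


def _data_path(name: str):
    return resources.files("dvmuq.data").joinpath(name)


def default_parameter_table(
    k_mort1_range: tuple[float, float] | None = None,
) -> list[ParameterSpec]:
    """The 13 published parameter specifications, in canonical order.

    The shipped table prints a degenerate range ``[0.01, 0.01]`` for the
    asymptotic maximum mortality rate ``k_mort1`` — an evident typographical
    error (it would make the parameter unsampleable while it carries nonzero
    sensitivity in the published ranking).  The loader repairs it to
    ``K_MORT1_REPAIRED_RANGE`` and warns; pass ``k_mort1_range`` to override.
    """
    with resources.as_file(_data_path("parameters.csv")) as p:
        table = pd.read_csv(p, comment="#")
    specs: list[ParameterSpec] = []
    for row in table.itertuples(index=False):
        lower, upper = float(row.lower), float(row.upper)
        if row.name == "k_mort1" and lower == upper:
            lower, upper = (
                k_mort1_range if k_mort1_range is not None else K_MORT1_REPAIRED_RANGE
            )
            warnings.warn(
                "k_mort1 ships with the degenerate printed range [0.01, 0.01]; "
                f"using repaired range [{lower}, {upper}] instead",
                UserWarning,
                stacklevel=2,
            )
        specs.append(
            ParameterSpec(
                name=str(row.name),
                standard=float(row.standard),
                lower=lower,
                upper=upper,
                description=str(row.description),
            )
        )
    order = {name: i for i, name in enumerate(PARAMETER_ORDER)}
    specs.sort(key=lambda s: order[s.name])
    if len(specs) != 13:
        raise InvalidSpecError(f"expected 13 parameter specs, got {len(specs)}")
    return specs


def standard_values(specs: Sequence[ParameterSpec] | None = None) -> dict[str, float]:
    """Mapping of parameter name to its standard (control-run) value."""
    if specs is None:
        specs = default_parameter_table()
    return {s.name: s.standard for s in specs}


def lhs_sample(
    specs: Sequence[ParameterSpec], n: int, seed: int
) -> SampleMatrix:
    """Draw a stratified Latin hypercube sample of the parameter space.

    For every parameter the range is split into ``n`` equal-width strata
    (equal probability under the uniform distribution); one value is drawn
    uniformly at random within each stratum; the per-parameter draws are
    then randomly permuted, column by column, to form ``n`` joint samples.
    Deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError(f"sample count must be positive, got {n}")
    for spec in specs:
        if spec.width <= 0:
            raise InvalidSpecError(f"parameter {spec.name!r} has a degenerate range")
    rng = np.random.default_rng(seed)
    k = len(specs)
    values = np.empty((n, k))
    edges01 = np.arange(n) / n
    for j, spec in enumerate(specs):
        # one uniform draw inside each of the n strata, then a random pairing
        within = rng.random(n) / n
        stratified01 = edges01 + within
        col = spec.lower + stratified01 * spec.width
        values[:, j] = rng.permutation(col)
    return SampleMatrix(values=values, param_names=[s.name for s in specs], seed=seed)


def stratum_index(x: np.ndarray, spec: ParameterSpec, n: int) -> np.ndarray:
    """Index of the stratum containing each value; strata are [a, b) with the
    final stratum closed at the upper bound."""
    idx = np.floor((np.asarray(x) - spec.lower) / spec.width * n).astype(int)
    return np.clip(idx, 0, n - 1)


def check_stratification(
    matrix: SampleMatrix, specs: Sequence[ParameterSpec]
) -> StratificationReport:
    """Verify that every column occupies each of the ``n`` strata exactly once."""
    if matrix.values.shape[1] != len(specs):
        raise ValueError(
            f"matrix has {matrix.values.shape[1]} columns but {len(specs)} specs given"
        )
    n = matrix.n_samples
    column_pass: dict[str, bool] = {}
    offending: dict[str, list[int]] = {}
    for j, spec in enumerate(specs):
        counts = np.bincount(stratum_index(matrix.values[:, j], spec, n), minlength=n)
        bad = np.nonzero(counts != 1)[0]
        column_pass[spec.name] = bad.size == 0
        if bad.size:
            offending[spec.name] = bad.tolist()
    return StratificationReport(
        passed=all(column_pass.values()),
        column_pass=column_pass,
        offending_strata=offending,
    )


# ---------------------------------------------------------------------------
# persistence

def save_sample_matrix(matrix: SampleMatrix, path: str | Path) -> None:
    """Write the sample matrix as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    matrix.to_frame().to_csv(path, index_label="sample_id")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps({"seed": matrix.seed, "n": matrix.n_samples}, indent=2)
    )


def load_sample_matrix(path: str | Path) -> SampleMatrix:
    path = Path(path)
    frame = pd.read_csv(path, index_col="sample_id")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {"seed": -1}
    return SampleMatrix(
        values=frame.to_numpy(),
        param_names=list(frame.columns),
        seed=int(meta["seed"]),
        sample_ids=frame.index.to_numpy(),
    )
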
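"""Model parameters: the uncertain-input registry and fixed constants.

Uncertain inputs (probabilities, costs, utilities, the complication-cost
fold) live in ``data/table1.yaml``, each with a base value, a plausible
range and a PSA distribution family; they are the units of one-way and
probabilistic sensitivity analysis.  The refit trial survival parameters
and the economic settings are structural constants: they were selected
once (AIC/BIC over four candidate families) and are not varied in
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .survival import Family, SurvivalModel

__all__ = [
    "Parameter",
    "load_parameters",
    "base_values",
    "GDP_PER_CAPITA_CHINA_2018",
    "DEFAULT_WTP",
    "SURVIVAL_MODELS",
]

#: 2018 Chinese per-capita GDP, US$; the WTP threshold is three times this.
GDP_PER_CAPITA_CHINA_2018 = 9770.85
DEFAULT_WTP = round(3 * GDP_PER_CAPITA_CHINA_2018)  # 29,313 US$/QALY

#: Refit trial survival curves (monthly time axis).
SURVIVAL_MODELS = {
    # disease-free survival after curative gastrectomy + adjuvant chemo (CLASSIC)
    "curative_progression": SurvivalModel(Family.WEIBULL, (0.0132, 0.8454)),
    # PFS, palliative gastrectomy + chemotherapy arm (REGATTA)
    "palliative_surgery_progression": SurvivalModel(Family.LOGLOGISTIC, (0.0142, 2.0360)),
    # PFS, chemotherapy-alone arm (REGATTA)
    "chemotherapy_progression": SurvivalModel(Family.LOGLOGISTIC, (0.0069, 2.3024)),
    # overall survival from progression (COUGAR-02 docetaxel arm)
    "pd_death": SurvivalModel(Family.WEIBULL, (0.0654, 1.3663)),
}

_DISTS = {"beta", "gamma", "normal", "fixed"}


@dataclass(frozen=True)
class Parameter:
    """One uncertain model input: base value, range, PSA distribution."""

    id: str
    base: float
    low: float
    high: float
    dist: str
    role: str

    def __post_init__(self) -> None:
        if self.dist not in _DISTS:
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.dist != "fixed" and not self.low <= self.base <= self.high:
            raise ValueError(f"{self.id}: need low <= base <= high")


def load_parameters(path: str | Path | None = None) -> list[Parameter]:
    """Load the parameter table (YAML or CSV); bundled defaults when None."""
    if path is None:
        text = (resources.files("gc_cea") / "data" / "table1.yaml").read_text()
        raw = yaml.safe_load(text)["parameters"]
    else:
        path = Path(path)
        if path.suffix.lower() in {".yaml", ".yml"}:
            raw = yaml.safe_load(path.read_text())["parameters"]
        else:
            raw = pd.read_csv(path).to_dict("records")
    params = [Parameter(**{k: row[k] for k in ("id", "base", "low", "high", "dist", "role")})
              for row in raw]
    ids = [p.id for p in params]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate parameter ids")
    return params


def base_values(params: list[Parameter] | None = None) -> dict[str, float]:
    """Map id -> base-case value."""
    if params is None:
        params = load_parameters()
    return {p.id: float(p.base) for p in params}
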
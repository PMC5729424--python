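"""Indicator schema: variable names, groups, transforms, and score weights.

The default schema describes the 20 tract-level indicators used by the
California cumulative-impact screening method: 12 environmental variables
(7 exposures, 5 environmental effects), 5 socioeconomic vulnerability
variables, and 3 health-outcome variables.  Each variable carries the
normalizing transform applied before correlation/PCA/regression analysis
and the weight it receives in the composite score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

GROUPS = (
    "environmental_exposure",
    "environmental_effect",
    "socioeconomic",
    "health_outcome",
)

TRANSFORM_KINDS = ("none", "log10", "cube_root", "sqrt", "arcsine_sqrt")


@dataclass(frozen=True)
class Variable:
    """One indicator variable.

    Parameters
    ----------
    name : column name in indicator tables.
    group : one of :data:`GROUPS`.
    transform : normalizing transform kind (see :mod:`envscreen.transforms`).
    weight : nonnegative weight in the composite-score group average.
    direction : +1 if larger raw values mean greater hazard, -1 otherwise.
    offset : additive offset applied before log10/sqrt (zero handling).
    is_percentage : True if the source reports a percentage that must be
        divided by 100 before an arcsine-square-root transform.
    """

    name: str
    group: str
    transform: str = "none"
    weight: float = 1.0
    direction: int = 1
    offset: float = 0.0
    is_percentage: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.name}")
        if self.transform not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform {self.transform!r} for {self.name}")
        if self.weight < 0:
            raise ValueError(f"negative weight for {self.name}")
        if self.offset != 0.0 and self.transform not in ("log10", "sqrt"):
            raise ValueError(f"offset only valid for log10/sqrt ({self.name})")


@dataclass
class IndicatorSchema:
    """Ordered collection of :class:`Variable` with group lookups."""

    variables: list[Variable] = field(default_factory=list)
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def __iter__(self):
        return iter(self.variables)

    def group(self, *groups: str) -> list[str]:
        """Names of variables whose group is in ``groups``."""
        return [v.name for v in self.variables if v.group in groups]

    @property
    def environmental(self) -> list[str]:
        return self.group("environmental_exposure", "environmental_effect")

    @property
    def socioeconomic(self) -> list[str]:
        return self.group("socioeconomic")

    @property
    def health_outcome(self) -> list[str]:
        return self.group("health_outcome")

    @property
    def population_chars(self) -> list[str]:
        """Socioeconomic + health-outcome variables (the 'population' block)."""
        return self.group("socioeconomic", "health_outcome")

    def subset(self, which: str) -> list[str]:
        """Resolve a named variable subset: env | soc | all17 | all20."""
        table = {
            "env": self.environmental,
            "soc": self.socioeconomic,
            "all17": self.environmental + self.socioeconomic,
            "all20": self.names,
        }
        try:
            return table[which]
        except KeyError:
            raise ValueError(f"unknown subset {which!r}; use env|soc|all17|all20")

    def resolve(self, column: str) -> str | None:
        """Map a file column name to a schema name via the alias table."""
        if column in self:
            return column
        return self.aliases.get(column)

    def to_json(self, path=None) -> str:
        payload = {
            "variables": [asdict(v) for v in self.variables],
            "aliases": self.aliases,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "IndicatorSchema":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        variables = [Variable(**v) for v in payload["variables"]]
        return cls(variables=variables, aliases=payload.get("aliases", {}))


def default_schema() -> IndicatorSchema:
    """The default 20-variable schema.

    Weight convention: exposures full weight, environmental effects half
    weight, population variables full weight.  Transform assignment honors
    the published transform counts (7 log10, 6 cube root, 5 square root
    counting the Over65 covariate, arcsine square root for drinking water;
    PM2.5 and low birth weight untransformed) and is fully configurable.
    """
    exposures = [
        Variable("ozone", "environmental_exposure", "sqrt"),
        Variable("pm25", "environmental_exposure", "none"),
        Variable("diesel_pm", "environmental_exposure", "log10", offset=1.0),
        Variable("traffic", "environmental_exposure", "log10", offset=1.0),
        Variable("drinking_water", "environmental_exposure", "arcsine_sqrt"),
        Variable("pesticides", "environmental_exposure", "log10", offset=1.0),
        Variable("toxic_release", "environmental_exposure", "log10", offset=1.0),
    ]
    effects = [
        Variable("cleanup_sites", "environmental_effect", "log10", 0.5, offset=1.0),
        Variable("groundwater_threats", "environmental_effect", "log10", 0.5, offset=1.0),
        Variable("haz_waste", "environmental_effect", "log10", 0.5, offset=1.0),
        Variable("impaired_water", "environmental_effect", "cube_root", 0.5),
        Variable("solid_waste", "environmental_effect", "cube_root", 0.5),
    ]
    socio = [
        Variable("education", "socioeconomic", "sqrt"),
        Variable("linguistic_isolation", "socioeconomic", "cube_root"),
        Variable("poverty", "socioeconomic", "sqrt"),
        Variable("unemployment", "socioeconomic", "cube_root"),
        Variable("housing_burden", "socioeconomic", "sqrt"),
    ]
    health = [
        Variable("asthma", "health_outcome", "cube_root"),
        Variable("low_birth_weight", "health_outcome", "none"),
        Variable("cardiovascular", "health_outcome", "cube_root"),
    ]
    return IndicatorSchema(variables=exposures + effects + socio + health)


def validate_default(schema: IndicatorSchema) -> None:
    """Check the 12/5/3 group counts expected of a default-style schema."""
    n_env = len(schema.environmental)
    n_soc = len(schema.socioeconomic)
    n_health = len(schema.health_outcome)
    if (n_env, n_soc, n_health) != (12, 5, 3):
        raise ValueError(
            f"expected 12 environmental / 5 socioeconomic / 3 health variables, "
            f"got {n_env}/{n_soc}/{n_health}"
        )
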
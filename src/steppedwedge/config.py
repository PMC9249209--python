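"""Pipeline configuration: one YAML file drives everything.

Sections (all optional except ``design``): ``design`` (trial design
fields), ``cohort`` (parametric generator parameters), ``replica``
(count identities + optional spike), ``analyses`` (list of
``{code, adjust}`` pairs), ``augmentation`` (prior spec), ``sensitivity``
(tipping-point settings), ``simstudy`` (scenario settings), plus a global
``seed`` and ``output_dir``.  Command-line flags override config values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .analyses import ADJUSTMENT_METHODS, MODEL_CODES
from .augment import PriorSpec
from .cohort import CohortParams, ReplicaCounts
from .design import TrialDesign, default_design


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    design: TrialDesign
    cohort: CohortParams = field(default_factory=CohortParams)
    replica: ReplicaCounts | None = None
    analyses: list = field(default_factory=list)          # [(code, adjustment)]
    augmentation: PriorSpec | None = None
    sensitivity: dict | None = None
    simstudy: dict | None = None
    seed: int = 0
    output_dir: str = "results"
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self):
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _require(d, key, context):
    if key not in d:
        raise ConfigError(f"missing required key {key!r} in section {context!r}")
    return d[key]


def parse_config(raw: dict) -> PipelineConfig:
    if "design" not in raw:
        raise ConfigError("missing required section 'design'")
    dsec = raw["design"]
    if dsec == "default":
        design = default_design()
    else:
        try:
            design = TrialDesign.from_dict(dsec)
        except (TypeError, KeyError, ValueError) as err:
            raise ConfigError(f"invalid 'design' section: {err}") from err

    cohort = CohortParams(**raw.get("cohort", {})) if isinstance(raw.get("cohort", {}), dict) \
        else raw["cohort"]
    try:
        cohort.validate()
    except ValueError as err:
        raise ConfigError(f"invalid 'cohort' section: {err}") from err

    replica = None
    if "replica" in raw:
        rsec = dict(raw["replica"])
        for key in ("phase_denominators", "phase_events", "randomisation_intervention",
                    "randomisation_control", "spike"):
            if key in rsec and rsec[key] is not None:
                rsec[key] = tuple(rsec[key])
        try:
            replica = ReplicaCounts(**rsec).validate()
        except (TypeError, ValueError) as err:
            raise ConfigError(f"invalid 'replica' section: {err}") from err

    analyses = []
    for item in raw.get("analyses", []):
        if isinstance(item, str):
            code, adjust = item, "none"
        else:
            code = _require(item, "code", "analyses")
            adjust = item.get("adjust", "none")
        if code not in MODEL_CODES:
            raise ConfigError(f"unknown analysis code {code!r} in 'analyses' "
                              f"(choose from {'/'.join(MODEL_CODES)})")
        if adjust not in ADJUSTMENT_METHODS:
            raise ConfigError(f"unknown adjustment {adjust!r} in 'analyses' "
                              f"(choose from {'/'.join(ADJUSTMENT_METHODS)})")
        analyses.append((code, adjust))

    augmentation = None
    if "augmentation" in raw:
        try:
            augmentation = PriorSpec(**{
                k: tuple(v) if k == "offset_days" else v
                for k, v in dict(raw["augmentation"]).items()
            }).validate()
        except (TypeError, ValueError) as err:
            raise ConfigError(f"invalid 'augmentation' section: {err}") from err

    return PipelineConfig(
        design=design, cohort=cohort, replica=replica, analyses=analyses,
        augmentation=augmentation,
        sensitivity=raw.get("sensitivity"), simstudy=raw.get("simstudy"),
        seed=int(raw.get("seed", 0)), output_dir=raw.get("output_dir", "results"),
        raw=raw,
    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping at the top level")
    return parse_config(raw)


__all__ = ["PipelineConfig", "ConfigError", "parse_config", "load_config"]
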
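"""The 24-model catalog: 4 polymorphs x 3 binding sites x 2 Cu:AS ratios.

Model ids follow the study's convention: letter = polymorph (A-D); numbers
1-3 are the low-concentration (Cu:AS 1:2) models and 4-6 the
high-concentration (1:1) models; within each triple the number encodes the
binding site (1/4 N-terminal, 2/5 His50, 3/6 C-terminal).
"""

from __future__ import annotations

from .synthetic import BindingSite, CuASRatio, ModelSpec, Polymorph

SIMULATION_LENGTH_NS = 200.0
SAVE_INTERVAL_PS = 10.0
ENERGY_WINDOW_NS = 5.0


def catalog_from_table1() -> list[ModelSpec]:
    """All 24 models in id order (A1..A6, B1..B6, C1..C6, D1..D6)."""
    out = []
    for poly in Polymorph:
        for ratio in (CuASRatio.LOW, CuASRatio.HIGH):
            for site in (BindingSite.NTERM, BindingSite.HIS50,
                         BindingSite.CTERM):
                out.append(ModelSpec(poly, site, ratio))
    return out


def model_by_id(model_id: str) -> ModelSpec:
    return ModelSpec.from_model_id(model_id)


def concentration_groups(models: list[ModelSpec]) -> dict[str, list[ModelSpec]]:
    """Partition by Cu:AS ratio; population analyses never mix the two
    groups (their systems differ in atom count)."""
    return {"low": [m for m in models if m.cu_as_ratio is CuASRatio.LOW],
            "high": [m for m in models if m.cu_as_ratio is CuASRatio.HIGH]}


def total_simulated_ns(models: list[ModelSpec],
                       ns_per_model: float = SIMULATION_LENGTH_NS) -> float:
    return len(models) * ns_per_model
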
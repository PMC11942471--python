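import numpy as np
import pandas as pd
import pytest

from effi.io import as_record_table, harmonize, impute_linear
from effi.indicators import compute_indicators
from effi.synthetic import SyntheticConfig, generate


def make_records(source, rows):
    df = pd.DataFrame(rows, columns=["department", "year", "category", "count"])
    return as_record_table(df, source)


@pytest.fixture(scope="session")
def synthetic_run():
    """One deterministic default-condition synthetic draw, harmonized and imputed."""
    cfg = SyntheticConfig(seed=11)
    tables, truth = generate(cfg)
    panel = harmonize(
        tables.values(),
        departments=sorted(truth.fragility.index),
        years=cfg.years,
    )
    panel = impute_linear(panel)
    return cfg, tables, truth, panel


@pytest.fixture(scope="session")
def indicator_panel(synthetic_run):
    _, _, _, panel = synthetic_run
    return compute_indicators(panel)


@pytest.fixture()
def tiny_counts():
    """2 departments x 2 years of hand-written counts covering all aggregates."""
    depts, years = ["D01", "D02"], [2020, 2021]
    rows = {"births": [], "affiliations": [], "violence": [], "deaths": []}
    base = {
        "births_le14": 2,
        "births_15_19": 30,
        "aff_women_10_14": 1000,
        "aff_women_15_19": 1000,
        "aff_women_total": 20000,
        "aff_indigenous": 500,
        "aff_migrant": 50,
        "aff_subsidized": 12000,
        "dv_total": 100,
        "dv_women_male_perp": 30,
        "dv_children_le18": 10,
        "deaths_total": 1000,
        "deaths_suicide": 5,
        "deaths_homicide_le19": 25,
    }
    source_of = {
        "births": ("births_le14", "births_15_19"),
        "affiliations": (
            "aff_women_10_14",
            "aff_women_15_19",
            "aff_women_total",
            "aff_indigenous",
            "aff_migrant",
            "aff_subsidized",
        ),
        "violence": ("dv_total", "dv_women_male_perp", "dv_children_le18"),
        "deaths": ("deaths_total", "deaths_suicide", "deaths_homicide_le19"),
    }
    for src, cats in source_of.items():
        for d in depts:
            for y in years:
                for c in cats:
                    rows[src].append((d, y, c, base[c]))
    return {src: make_records(src, r) for src, r in rows.items()}
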
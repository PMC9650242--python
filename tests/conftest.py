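"""Shared fixtures: configs, the worked-example cohort, and random cohorts."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest
from hypothesis import settings

import icusepsis as ic
from icusepsis.synthetic import GroundTruth

settings.register_profile("default", derandomize=True, max_examples=200)
settings.load_profile("default")

TABLE_NAMES = ("admissions", "drugitems", "numericitems", "listitems")


@dataclass
class Cohort:
    """A generated cohort plus everything the pipeline computed from it."""

    spec: ic.ScenarioSpec
    tables_dir: object
    store: ic.EventStore
    truth: GroundTruth
    sofa: pd.DataFrame
    flags: pd.DataFrame


def build_cohort(spec: ic.ScenarioSpec, out_dir) -> Cohort:
    tables, truth = ic.generate(spec, out_dir=out_dir)
    store = ic.read_tables(
        {name: out_dir / f"{name}.csv" for name in TABLE_NAMES}, ic.default_concept_map()
    )
    sofa, flags = ic.run_pipeline(
        store,
        ic.default_thresholds(),
        ic.default_rank_map(),
        ic.default_shock_criteria(),
        day_range=spec.day_range,
    )
    return Cohort(spec=spec, tables_dir=out_dir, store=store, truth=truth,
                  sofa=sofa, flags=flags)


@pytest.fixture(scope="session")
def thresholds():
    return ic.default_thresholds()


@pytest.fixture(scope="session")
def rank_map():
    return ic.default_rank_map()


@pytest.fixture(scope="session")
def shock_criteria():
    return ic.default_shock_criteria()


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory) -> Cohort:
    out = tmp_path_factory.mktemp("worked_example")
    return build_cohort(ic.tables23_fixture(), out)


@pytest.fixture(scope="session")
def random_cohort_250(tmp_path_factory) -> Cohort:
    out = tmp_path_factory.mktemp("cohort250")
    return build_cohort(ic.random_cohort(250, seed=7), out)


@pytest.fixture(scope="session")
def matched_cohort(tmp_path_factory) -> Cohort:
    out = tmp_path_factory.mktemp("matched")
    return build_cohort(ic.random_cohort(200, seed=11, baseline_mode="match"), out)
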
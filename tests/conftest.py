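"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from dietpoll import (
    HouseholdTable,
    SyntheticConfig,
    Variable,
    VariableCodebook,
    generate,
    toy_fixture,
)


@pytest.fixture(scope="session")
def toy():
    return toy_fixture()


@pytest.fixture(scope="session")
def small_table():
    """A 2000-record synthetic table with the default treatment model."""
    return generate(SyntheticConfig(n=2000, include_items=False), seed=42)


@pytest.fixture
def simple_codebook():
    return VariableCodebook.from_variables([
        Variable("region", ("north", "south"), "covariate"),
        Variable("wealth", ("poor", "rich"), "covariate"),
    ])


def make_table(df: pd.DataFrame, codebook: VariableCodebook) -> HouseholdTable:
    """Build a validated table, filling reserved columns with defaults."""
    df = df.copy()
    if "id" not in df:
        df["id"] = [f"r{i}" for i in range(len(df))]
    if "weight" not in df:
        df["weight"] = 1.0
    for col, default in (("diet_class", 0), ("stunting", 0),
                         ("child_age_months", 12), ("interview_day", 0)):
        if col not in df:
            df[col] = default
    t = HouseholdTable(df, codebook)
    t.validate()
    return t


# ----------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ----------------------------------------------------------------------
def naive_kernel_counterfactuals(p_t, p_c, y_c, w_c, h):
    """O(n^2) Epanechnikov counterfactuals, the direct double loop."""
    cf = np.full(len(p_t), np.nan)
    for i, pi in enumerate(p_t):
        u = (p_c - pi) / h
        k = np.where(np.abs(u) < 1, 0.75 * (1 - u ** 2), 0.0) * w_c
        if k.sum() > 0:
            cf[i] = np.dot(k, y_c) / k.sum()
    return cf


def naive_kernel_att(p_t, y_t, w_t, p_c, y_c, w_c, h):
    cf = naive_kernel_counterfactuals(p_t, p_c, y_c, w_c, h)
    ok = np.isfinite(cf)
    om = w_t[ok] / w_t[ok].sum()
    return float(np.dot(om, y_t[ok] - cf[ok]))


def stratified_att(strata_t, y_t, w_t, strata_c, y_c, w_c):
    """Exact stratified difference-of-means ATT over discrete strata."""
    total = 0.0
    mass = 0.0
    for s in np.unique(strata_t):
        mt = strata_t == s
        mc = strata_c == s
        if not mc.any():
            continue
        wt = w_t[mt].sum()
        diff = (np.dot(w_t[mt], y_t[mt]) / wt
                - np.dot(w_c[mc], y_c[mc]) / w_c[mc].sum())
        total += wt * diff
        mass += wt
    return total / mass
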
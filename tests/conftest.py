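import numpy as np
import pandas as pd
import pytest

from wastingshocks import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_countries=6,
        children_per_round=150,
        rounds_min=2,
        rounds_max=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def mech_ds(small_cfg):
    return generate_dataset(small_cfg, mechanisms=True)


def brute_force_cluster_vcov(X, y, w, clusters, small_sample=True):
    """Independent direct-formula sandwich: explicit inverse, per-cluster
    outer products in a Python loop. Deliberately naive."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    n, k = X.shape
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.inv(xtwx) @ (X.T @ W @ y)
    e = y - X @ beta
    labels = np.unique(clusters)
    meat = np.zeros((k, k))
    for g in labels:
        m = clusters == g
        s_g = (X[m] * (w[m] * e[m])[:, None]).sum(axis=0)
        meat += np.outer(s_g, s_g)
    G = len(labels)
    c = (G / (G - 1)) * ((n - 1) / (n - k)) if small_sample else 1.0
    inv = np.linalg.inv(xtwx)
    return beta, c * inv @ meat @ inv


def random_cluster_instance(rng, n_max=200):
    """Small random WLS instance for oracle-equivalence checks."""
    n = int(rng.integers(12, n_max + 1))
    k = int(rng.integers(2, 6))
    G = int(rng.integers(3, max(4, n // 4)))
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = rng.normal(size=k)
    clusters = rng.integers(0, G, size=n)
    u = rng.normal(size=G)[clusters] + rng.normal(size=n)
    y = X @ beta + u
    w = rng.uniform(0.2, 3.0, size=n)
    return X, y, w, clusters


@pytest.fixture
def tiny_children() -> pd.DataFrame:
    """Hand-built two-country, multi-round children table."""
    rows = []
    rng = np.random.default_rng(5)
    for country, region, rounds in [
        ("AA", "South Asia", {"AA-r1": (2005, 100), "AA-r2": (2010, 300)}),
        ("BB", "Sahel & Horn", {"BB-r1": (2008, 200)}),
    ]:
        for rid, (year, size) in rounds.items():
            for _ in range(size):
                rows.append(
                    {
                        "country": country,
                        "region": region,
                        "round_id": rid,
                        "interview_year": year,
                        "interview_month": int(rng.integers(1, 13)),
                        "age_months": int(rng.integers(0, 60)),
                        "wasting_any": int(rng.random() < 0.3),
                        "wasting_mod_sev": int(rng.random() < 0.15),
                        "wasting_severe": int(rng.random() < 0.05),
                        "asset_class": rng.choice(["none", "some", "all"]),
                        "maternal_education_years": int(rng.integers(0, 12)),
                        "piped_water": int(rng.random() < 0.4),
                        "flush_toilet": int(rng.random() < 0.3),
                        "facility_birth": int(rng.random() < 0.5),
                        "anc4": int(rng.random() < 0.4),
                        "fully_vaccinated": int(rng.random() < 0.6),
                        "teen_birth": int(rng.random() < 0.2),
                        "parity_4plus": int(rng.random() < 0.3),
                        "female": int(rng.random() < 0.5),
                        "rural": int(rng.random() < 0.6),
                        "design_weight": 1.0,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "country": ["AA", "BB"],
            "region": ["South Asia", "Sahel & Horn"],
            "pop_u5": [2_000_000, 2_000_000],
            "mean_prev_any": [30.0, 30.0],
            "mean_prev_mod_sev": [15.0, 15.0],
            "mean_prev_severe": [5.0, 5.0],
        }
    )
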
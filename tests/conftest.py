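"""Shared fixtures, hypothesis configuration and the brute-force index oracle."""

from __future__ import annotations

import math

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from ethnosurvey.use_reports import Survey, UseReport

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_survey(triples, informants=None, categories=None):
    """Survey from raw (informant, species, category) triples."""
    reports = [UseReport(i, s, c) for i, s, c in triples]
    return Survey.from_reports(reports, informants=informants, use_categories=categories)


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle for the index table, independent of the
# package implementation: plain dict/set arithmetic straight from the
# definitions, plus naive O(S^2) competition ranking.
# ---------------------------------------------------------------------------

def oracle_index_table(triples, n, nc, convention="raw_rfc"):
    """species -> dict of index values and ranks, from first principles."""
    triples = sorted(set(triples))
    species = sorted({s for _, s, _ in triples})
    if not species:
        return {}
    values = {}
    for s in species:
        mine = [(i, c) for i, sp, c in triples if sp == s]
        fc = len({i for i, _ in mine})
        nu = len({c for _, c in mine})
        uv = len(mine) / n
        cii = len(mine) / n
        rfc = fc / n
        values[s] = {"fc": fc, "nu": nu, "uv": uv, "cii": cii, "rfc": rfc}
    rfc_max = max(v["rfc"] for v in values.values())
    nu_max = max(v["nu"] for v in values.values())
    for s, v in values.items():
        rnu = v["nu"] / nu_max
        rfc_term = v["rfc"] / rfc_max if convention == "normalized" else v["rfc"]
        v["rnu"] = rnu
        v["ri"] = (rfc_term + rnu) / 2
        v["cvi"] = (v["nu"] / nc) * (v["fc"] / n) * v["cii"]
    for key in ("rfc", "ri", "cii", "cvi"):
        for s in species:
            # competition rank: 1 + number of species strictly greater
            values[s][f"rank_{key}"] = 1 + sum(
                1 for other in species if values[other][key] > values[s][key]
            )
    return values


# Strategy for small random surveys (bounded universes, unique triples).
small_survey_triples = st.lists(
    st.tuples(
        st.sampled_from(["i1", "i2", "i3", "i4", "i5"]),
        st.sampled_from(["sp_a", "sp_b", "sp_c", "sp_d"]),
        st.sampled_from(["c1", "c2", "c3"]),
    ),
    min_size=1,
    max_size=25,
    unique=True,
)


@pytest.fixture
def toy_survey():
    """Two informants, two species, hand-checkable counts."""
    return make_survey(
        [
            ("A", "Aloe vera", "digestive"),
            ("A", "Aloe vera", "skin"),
            ("B", "Aloe vera", "digestive"),
            ("B", "Centella asiatica", "skin"),
        ]
    )
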
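"""Bundled reference data: a published 21-eye OAG cohort with control summaries.

Four small CSVs ship with the package:

* ``oag_cohort.csv`` — per-eye regional mfPhNR RAD (nV/deg^2) and GCL
  thickness (um) for 21 open-angle glaucoma eyes;
* ``normative_limits.csv`` — the control-derived one-sided lower 95%
  normative limit per region and measure;
* ``group_summaries.csv`` — mean/SD/n per group, region and measure
  (controls n=20, patients n=21);
* ``regression_expected.csv`` — the published structure-function regression
  estimates used for reconciliation.

Known quirks of the printed source recorded here so downstream reports can
surface them: the OAG GCL Area 3 summary mean is restored to 20.190 (a digit
was dropped in print); the printed ST-sector GCL abnormal count (19) exceeds
the count obtained from the printed individual values and limit (18).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# (region_type, region) pairs coupling a functional RAD region to its
# structurally corresponding GCL region.
REGION_PAIRS = (
    (("ring", "R1"), ("area", "Area1")),
    (("ring", "R2"), ("area", "Area2")),
    (("ring", "R3+R4"), ("area", "Area3")),
    (("sector", "ST"), ("sector", "ST")),
    (("sector", "IT"), ("sector", "IT")),
    (("sector", "IN"), ("sector", "IN")),
    (("sector", "SN"), ("sector", "SN")),
)

FIXTURE_NOTES = (
    "OAG GCL Area3 summary mean restored to 20.190 (printed with a dropped digit)",
    "printed ST-sector GCL abnormal count (19/21) disagrees with the printed "
    "individual values vs the printed limit (18/21)",
    "published ring-trend coefficients for mfPhNR (-5.20 OAG / -9.28 controls) "
    "are not reproducible from the ring means and are not independently verified",
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("mfphnr.data").joinpath(name).open() as f:
        return pd.read_csv(f, comment="#")


def load_reference_cohort() -> pd.DataFrame:
    """Tidy per-eye cohort table of the 21 OAG eyes (294 rows)."""
    return _read("oag_cohort.csv")


def load_reference_limits() -> pd.DataFrame:
    """Published control-derived lower normative limits per region/measure."""
    return _read("normative_limits.csv")


def load_reference_summaries() -> pd.DataFrame:
    """Published group means/SDs/n per region and measure for both groups."""
    return _read("group_summaries.csv")


def load_reference_regressions() -> pd.DataFrame:
    """Published OAG regression estimates (slope, 95% CI, R^2, p)."""
    return _read("regression_expected.csv")
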
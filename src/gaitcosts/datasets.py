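"""Packaged worked-example data.

``load_table1`` returns the per-participant worked example shipped with
the package: for ten participants, the pre-transition incline grade and
the crouch / pre-transition-incline values of metabolic power and the
three activation costs, each expressed as a percentage of that
participant's level (0% incline) walking value. Two participants have
missing activation entries (EMG excluded for signal artefact).
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import pandas as pd

from .ccp import CcpResult, ccp_from_percent

__all__ = ["load_table1", "table1_ccp_results"]


def load_table1() -> pd.DataFrame:
    """Load the worked-example cost table (percent of level walking)."""
    with resources.files("gaitcosts.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("participant")


def table1_ccp_results(df: Optional[pd.DataFrame] = None) -> list[CcpResult]:
    """Apply the CCP rule to the worked-example rows.

    The table's values are already percent-of-baseline, so the rule is
    applied directly; participants with missing activation data yield
    None CCP flags and NaN advantages.
    """
    if df is None:
        df = load_table1()
    results = []
    for pid, row in df.iterrows():
        crouch = {
            "c_met_p": row["cmet_crouch"],
            "c_a2": row["ca2_crouch"],
            "c_a_max": row["camax_crouch"],
            "c_a_vol": row["cavol_crouch"],
        }
        incline = {
            "c_met_p": row["cmet_pre"],
            "c_a2": row["ca2_pre"],
            "c_a_max": row["camax_pre"],
            "c_a_vol": row["cavol_pre"],
        }
        results.append(
            ccp_from_percent(
                str(pid),
                crouch,
                incline,
                pre_transition_grade=int(row["pre_transition_grade"]),
            )
        )
    return results
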
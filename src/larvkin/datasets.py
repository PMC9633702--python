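"""Published summary tables usable as inputs.

The study that motivates this package deposited no genotypes, but its
printed summary tables are sufficient input for all of the downstream
close-kin arithmetic: the distinct-parent-group tabulations per cohort
and the per-cohort sibling-status category counts.
"""

from __future__ import annotations

import numpy as np

from .sibgraph import DPGTabulation

__all__ = ["published_dpg_tabulations", "published_sibship_counts", "published_tow_table"]


def published_dpg_tabulations() -> dict[int, DPGTabulation]:
    """DPG size tabulations g_s for the 2016 and 2017 larval cohorts."""
    return {
        2016: DPGTabulation(2016, np.array([291, 9, 1, 0, 0, 0]), 156),
        2017: DPGTabulation(2017, np.array([398, 89, 12, 3, 2, 0]), 317),
    }


def published_sibship_counts() -> dict[int, dict]:
    """Per-cohort larva counts by sibling status (none / HS-only /
    FS-and-HS / FS-only)."""
    return {
        2016: {"n_none": 137, "n_hs_no_fs": 17, "n_fs_and_hs": 0, "n_fs_no_hs": 2},
        2017: {"n_none": 140, "n_hs_no_fs": 140, "n_fs_and_hs": 15, "n_fs_no_hs": 22},
    }


def published_tow_table() -> list[dict]:
    """A subset of tow stations with coordinates, for distance checks."""
    return [
        {"tow_id": "50748", "lon": -95.0126, "lat": 26.0295},
        {"tow_id": "50917", "lon": -89.0093, "lat": 28.0139},
        {"tow_id": "D03755/6", "lon": -87.767, "lat": 26.1216},
        {"tow_id": "D03791/2", "lon": -88.1328, "lat": 25.8438},
    ]
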
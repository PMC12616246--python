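"""Factorial condition designs keying every sample to its matched control."""

from __future__ import annotations

import itertools

import pandas as pd

ENGINEERING_STATES = ("unmodified", "stIL15")


def factorial_design(
    donors: list[str],
    engineering_states: list[str] = list(ENGINEERING_STATES),
    organoids: list[str] | None = None,
    antibody: list[bool] = [False],
    n_replicates: int = 1,
) -> pd.DataFrame:
    """One row per culture over the full factor cross.

    Monoculture designs pass ``organoids=None``; coculture designs cross
    donors x engineering x organoids x antibody x replicates.
    """
    orgs = organoids if organoids is not None else [None]
    rows = []
    for d, e, o, a, r in itertools.product(
        donors, engineering_states, orgs, antibody, range(1, n_replicates + 1)
    ):
        name = "_".join(
            p for p in (d, e, o, "mAb" if a else None, f"r{r}" if n_replicates > 1 else None) if p
        )
        rows.append(
            {
                "condition": name,
                "donor": d,
                "engineering": e,
                "organoid": o if o else "",
                "antibody": bool(a),
                "replicate": r,
            }
        )
    return pd.DataFrame(rows)


def monoculture_design(n_donors: int = 7, n_replicates: int = 3) -> pd.DataFrame:
    """γδ T-cell monoculture screen: donors x {unmodified, stIL15} x replicates."""
    donors = [chr(ord("A") + i) for i in range(n_donors)]
    return factorial_design(donors, list(ENGINEERING_STATES), None, [False], n_replicates)
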
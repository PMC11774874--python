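"""Published-table fixtures, machine-readable.

``table1_fixture`` returns the printed 9x9 phylogenetic Pearson
correlation matrix of the eight root traits plus mycorrhizal
colonization, with the printed significance flags.  ``table3_fixture``
returns the printed per-trait and whole-network parameters for the
networks with and without colonization.

The study's raw 32-species trait table is not published, so the
correlation fixture carries *indicator* p-values derived from the
printed significance marks (0.01 for marked pairs, 0.5 otherwise) —
enough for the standard |r| > threshold AND p < alpha retention rule to
reproduce the printed networks, but not the study's actual p-values.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .comparative import TraitCorrelations

__all__ = ["table1_fixture", "table3_fixture", "TABLE1_TRAITS"]

TABLE1_TRAITS = ("colM", "RD", "RTD", "SRA", "SRL", "RDMC", "RNC", "RC:N", "RCC")

_P_SIGNIFICANT = 0.01   # placeholder below any conventional alpha
_P_NONSIGNIFICANT = 0.5


def _read_fixture(name: str) -> str:
    return (resources.files("rhizonet") / "fixtures" / name).read_text()


def table1_fixture() -> TraitCorrelations:
    """The printed phylogenetic correlation matrix (n = 32 species)."""
    import io

    df = pd.read_csv(io.StringIO(_read_fixture("table1.csv")))
    names = list(TABLE1_TRAITS)
    p = len(names)
    r = np.eye(p)
    sig = np.zeros((p, p), dtype=bool)
    for row in df.itertuples(index=False):
        i, j = names.index(row.trait_a), names.index(row.trait_b)
        r[i, j] = r[j, i] = row.r
        sig[i, j] = sig[j, i] = bool(row.significant)
    pv = np.where(sig, _P_SIGNIFICANT, _P_NONSIGNIFICANT)
    np.fill_diagonal(pv, 1.0)
    return TraitCorrelations(names=tuple(names), mean=np.full(p, np.nan),
                             rate=r.copy(), corr=r, tvalues=None, pvalues=pv,
                             n=32, significant=sig)


def table3_fixture() -> dict:
    """Printed network parameters for both networks (one-decimal values)."""
    return json.loads(_read_fixture("table3.json"))
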
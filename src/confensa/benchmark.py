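"""Reproduction of the published EPAC1 numbers from SASBDB deposits.

The three deposited data sets (apo-EPAC1, cAMP:EPAC1 and the
cAMP:EPAC1:Rap1b ternary complex — SASBDB ids SASDCQ6, SASDCR6, SASDCS6)
are not redistributed with this package; place the subtracted curves as
``<id>.dat`` (3-column q/I/sigma, q in 1/A) and, where available, the
deposited rigid-body models as ``<id>.pdb`` under a local data directory
(default ``data/sasbdb``) to run the benchmark.  The analysis then
recomputes, per condition: Guinier Rg, Dmax from the indirect Fourier
transform, the volume-of-correlation molecular weight, and the Rg of the
deposited model.
"""

from __future__ import annotations

import os

from .curves import read_curve
from .invariants import guinier_fit, ift_pr, estimate_mw
from .structures import read_model, radius_of_gyration

__all__ = ["SASBDB_IDS", "run_benchmark"]

SASBDB_IDS = {"apo": "SASDCQ6", "camp": "SASDCR6", "ternary": "SASDCS6"}


def run_benchmark(data_dir: str = "data/sasbdb") -> dict:
    """Analyse whichever deposited data sets are present locally.

    Returns {condition: {rg, dmax, mw_vc_kda, model_rg}} with None for
    quantities whose input file is missing.  Raises FileNotFoundError if
    the directory contains none of the expected files.
    """
    out: dict = {}
    found = False
    for cond, sid in SASBDB_IDS.items():
        entry: dict = {"id": sid, "rg": None, "dmax": None,
                       "mw_vc_kda": None, "model_rg": None}
        dat = os.path.join(data_dir, f"{sid}.dat")
        if os.path.exists(dat):
            found = True
            curve = read_curve(dat)
            g = guinier_fit(curve)
            entry["rg"] = g.rg
            pr = ift_pr(curve)
            entry["dmax"] = pr.dmax
            mw = estimate_mw(curve, g)
            entry["mw_vc_kda"] = mw.mw_vc
        pdb = os.path.join(data_dir, f"{sid}.pdb")
        if os.path.exists(pdb):
            found = True
            entry["model_rg"] = radius_of_gyration(read_model(pdb))
        out[cond] = entry
    if not found:
        raise FileNotFoundError(
            f"no SASBDB files found under {data_dir!r}; download the "
            f"deposited curves/models ({', '.join(SASBDB_IDS.values())}) "
            "from sasbdb.org to run the benchmark")
    return out
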
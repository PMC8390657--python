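"""Target-decoy filtering of viral peptide-spectrum matches (PSMs).

Records carry an MSGF-style spectral probability (lower = better) and an
absolute precursor mass error in ppm.  The false-discovery rate at a pair of
cutoffs is #decoy / #target among the records passing both; the optimizer
grid-searches the observed cutoff values for the pair that maximizes passing
targets while keeping the FDR strictly below the limit (5% by default),
breaking ties toward the stricter score and then the stricter ppm cutoff.

For viral specificity, peptides identified in both the viral and the
non-viral search space are excluded; peptide identity for that comparison
strips modification annotations and collapses I/L (isobaric residues).

A per-record boolean ``manually_rejected`` column, when present, is honored
by dropping those records up front (manual spectral QC is out of scope).
"""
from __future__ import annotations

import re
from typing import Iterable

import numpy as np
import pandas as pd

DEFAULT_FDR_LIMIT = 0.05

REQUIRED_COLUMNS = ("is_decoy", "score", "ppm")


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"PSM table missing column {col!r}")
    if (records["score"] <= 0).any():
        raise ValueError("PSM scores must be > 0")
    if (records["ppm"] < 0).any():
        raise ValueError("ppm errors must be >= 0")
    if "manually_rejected" in records.columns:
        records = records[~records["manually_rejected"].astype(bool)]
    return records


def fdr_at(records: pd.DataFrame, score_cut: float,
           ppm_cut: float) -> float | None:
    """FDR = #decoy / #target among records with score <= and ppm <= the cuts.

    Returns ``None`` (an explicit undefined sentinel, never 0) when no
    target passes.
    """
    records = _validate(records)
    passing = records[(records["score"] <= score_cut)
                      & (records["ppm"] <= ppm_cut)]
    n_target = int((~passing["is_decoy"]).sum())
    n_decoy = int(passing["is_decoy"].sum())
    if n_target == 0:
        return None
    return n_decoy / n_target


def fdr_sweep(records: pd.DataFrame,
              ppm_cut: float = np.inf) -> pd.DataFrame:
    """FDR and monotonized q-value at every observed score cut (ppm fixed).

    The raw #decoy/#target FDR can dip when a loosened cut admits a target,
    so it is not monotone in the score cut; the q-value column is the
    running minimum of the FDR over all equal-or-looser cuts, which is
    non-decreasing as the cut loosens (standard target-decoy practice).
    Rows where no target passes carry an undefined (NaN) FDR.
    """
    records = _validate(records)
    sub = records[records["ppm"] <= ppm_cut]
    cuts = np.sort(sub["score"].unique())
    order = np.argsort(sub["score"].to_numpy(), kind="stable")
    d_sorted = sub["is_decoy"].to_numpy(dtype=bool)[order]
    s_sorted = sub["score"].to_numpy()[order]
    idx = np.searchsorted(s_sorted, cuts, side="right") - 1
    t = np.cumsum(~d_sorted)[idx]
    d = np.cumsum(d_sorted)[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(t > 0, d / np.maximum(t, 1), np.nan)
    q = np.array(fdr)
    # q(s) = min FDR over all cuts at least as loose as s
    valid = ~np.isnan(q)
    rev_min = np.minimum.accumulate(np.where(valid, q, np.inf)[::-1])[::-1]
    q = np.where(valid, rev_min, np.nan)
    return pd.DataFrame({"score_cut": cuts, "n_target": t, "n_decoy": d,
                         "fdr": fdr, "q_value": q})


def optimize_thresholds(records: pd.DataFrame,
                        fdr_limit: float = DEFAULT_FDR_LIMIT
                        ) -> tuple[float, float] | None:
    """Find (score_cut, ppm_cut) maximizing passing targets at FDR < limit.

    The grid is the observed (score, ppm) values.  Ties in the target count
    prefer the stricter (smaller) score cut, then the stricter ppm cut.
    Returns ``None`` with a warning when no pair is feasible.
    """
    records = _validate(records)
    if records.empty:
        raise ValueError("optimize_thresholds requires a non-empty table")
    scores = np.sort(records["score"].unique())
    ppms = np.sort(records["ppm"].unique())
    rec_scores = records["score"].to_numpy()
    rec_ppm = records["ppm"].to_numpy()
    is_decoy = records["is_decoy"].to_numpy(dtype=bool)
    order = np.argsort(rec_scores, kind="stable")
    s_sorted = rec_scores[order]
    d_sorted = is_decoy[order]
    p_sorted = rec_ppm[order]

    best: tuple[int, float, float] | None = None  # (-targets, score, ppm)
    for ppm_cut in ppms:
        keep = p_sorted <= ppm_cut
        cum_t = np.cumsum(keep & ~d_sorted)
        cum_d = np.cumsum(keep & d_sorted)
        # position of each candidate score cut in the sorted score array
        idx = np.searchsorted(s_sorted, scores, side="right") - 1
        t = cum_t[idx]
        d = cum_d[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = np.where(t > 0, d / np.maximum(t, 1), np.inf)
        feasible = (t > 0) & (fdr < fdr_limit)
        if not feasible.any():
            continue
        k = int(np.flatnonzero(feasible)[np.argmax(t[feasible])])
        # among equal target counts prefer the smallest feasible score cut
        same = feasible & (t == t[k])
        k = int(np.flatnonzero(same)[0])
        cand = (-int(t[k]), float(scores[k]), float(ppm_cut))
        if best is None or cand < best:
            best = cand
    if best is None:
        import logging
        logging.getLogger("soilvirome").warning(
            "optimize_thresholds: no feasible cutoff pair at FDR < %g",
            fdr_limit)
        return None
    return best[1], best[2]


_MOD_RE = re.compile(r"[^A-Za-z]")


def normalize_peptide(peptide: str) -> str:
    """Canonical peptide string: modifications stripped, I/L collapsed."""
    return _MOD_RE.sub("", peptide).upper().replace("I", "L")


def exclude_shared(viral_peptides: Iterable[str],
                   nonviral_peptides: Iterable[str]) -> list[str]:
    """Viral-only peptides: drop any whose normalized form occurs non-virally."""
    shared = {normalize_peptide(p) for p in nonviral_peptides}
    return [p for p in viral_peptides if normalize_peptide(p) not in shared]
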
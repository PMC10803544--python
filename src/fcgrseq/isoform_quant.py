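"""Isoform relative-abundance estimation by mixture-model EM.

Each read is scored against every reference isoform transcript with the
same global affine-gap alignment used for genotyping.  Compatibility
weights are exponentiated score differences, ``w_ij = exp(s_ij - max_j
s_ij)``: a read spanning a discriminating junction keeps weight for one
isoform only, while a read equally consistent with several isoforms keeps
equal weights and is apportioned fractionally by EM rather than discarded.

The per-animal abundances θ maximize the observed-data log-likelihood
``Σ_i log Σ_j θ_j w_ij`` via the standard EM update
``θ_j ← (1/R) Σ_i θ_j w_ij / Σ_k θ_k w_ik``, which never decreases the
likelihood.  Isoforms are reported when their abundance exceeds 1% in at
least one animal; carriers of an isoform are counted with the same 1%
default threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amplicon_caller import ScoringParams, alignment_score
from .cohort_stats import format_percent
from .gene_models import IsoformModel


@dataclass
class CompatibilityMatrix:
    weights: np.ndarray          # reads x isoforms
    isoform_ids: list[str]
    read_ids: list[str]
    n_dropped: int               # reads with no valid alignment


def compatibility_matrix(reads, isoforms: list[IsoformModel],
                         scoring: ScoringParams = ScoringParams()
                         ) -> CompatibilityMatrix:
    """Score reads against isoform transcripts and build EM weights."""
    if not isoforms:
        raise ValueError("at least one isoform is required")
    ids = [iso.isoform_id for iso in isoforms]
    kept_rows, kept_ids, dropped = [], [], 0
    for read_id, seq in reads:
        scores = np.array([alignment_score(seq, iso.transcript_seq, scoring)
                           for iso in isoforms], dtype=float)
        valid = scores >= scoring.min_score_per_base * len(seq)
        if not valid.any():
            dropped += 1
            continue
        scores[~valid] = -np.inf
        w = np.exp(scores - scores.max())
        kept_rows.append(w)
        kept_ids.append(read_id)
    weights = (np.vstack(kept_rows) if kept_rows
               else np.empty((0, len(ids))))
    return CompatibilityMatrix(weights, ids, kept_ids, dropped)


def em_abundance(matrix: CompatibilityMatrix | np.ndarray,
                 tol: float = 1e-8, max_iter: int = 1000
                 ) -> tuple[np.ndarray, bool]:
    """EM estimate of isoform proportions from a compatibility matrix.

    Returns ``(theta, converged)``; θ is nonnegative and sums to 1.
    Convergence is declared when the log-likelihood gain per iteration
    drops below ``tol``.
    """
    W = matrix.weights if isinstance(matrix, CompatibilityMatrix) else \
        np.asarray(matrix, dtype=float)
    R, K = W.shape
    if R < 1:
        raise ValueError("at least one read is required")
    if not np.isfinite(W).all() or (W < 0).any():
        raise ValueError("weights must be finite and nonnegative")
    if (W.sum(axis=1) <= 0).any():
        raise ValueError("every read row needs a positive entry")

    theta = np.full(K, 1.0 / K)
    prev_ll = -np.inf
    for _ in range(max_iter):
        mix = W @ theta                      # (R,)
        ll = float(np.log(mix).sum())
        resp = W * theta / mix[:, None]      # E-step responsibilities
        theta = resp.sum(axis=0) / R         # M-step
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            return theta, True
        prev_ll = ll
    return theta, False


def log_likelihood(W: np.ndarray, theta: np.ndarray) -> float:
    return float(np.log(W @ theta).sum())


def quantify_animal(reads, isoforms: list[IsoformModel],
                    scoring: ScoringParams = ScoringParams()) -> dict:
    """Per-animal isoform proportions for one gene."""
    cm = compatibility_matrix(reads, isoforms, scoring)
    theta, _ = em_abundance(cm)
    return dict(zip(cm.isoform_ids, theta))


def abundance_matrix(per_animal: dict[str, dict[str, float]]
                     ) -> pd.DataFrame:
    """Animals × isoforms abundance DataFrame from per-animal estimates."""
    return pd.DataFrame.from_dict(per_animal, orient="index").fillna(0.0)


def filter_isoform_set(abundance: pd.DataFrame,
                       min_abundance: float = 0.01) -> pd.DataFrame:
    """Keep isoforms above ``min_abundance`` in at least one animal.

    Abundances are *not* renormalized: the filter is a display mask.
    """
    keep = (abundance > min_abundance).any(axis=0)
    return abundance.loc[:, keep]


def isoform_carrier_stats(abundance: pd.DataFrame, cohort_size: int,
                          carrier_threshold: float = 0.01,
                          protein_ids: dict[str, str] | None = None
                          ) -> pd.DataFrame:
    """Per-isoform carrier counts and formatted percentages.

    An animal carries an isoform when its estimated abundance exceeds
    ``carrier_threshold``; isoforms with no carriers are omitted.
    """
    rows = []
    for iso in abundance.columns:
        n = int((abundance[iso] > carrier_threshold).sum())
        if n == 0:
            continue
        rows.append({
            "Nucleotide Isoform": iso,
            "Translated Protein Isoform": (protein_ids or {}).get(iso, ""),
            "Carriers": n,
            "% Carriers": (f"{format_percent(n, cohort_size)} "
                           f"({n}/{cohort_size})"),
        })
    df = pd.DataFrame(rows, columns=["Nucleotide Isoform",
                                     "Translated Protein Isoform",
                                     "Carriers", "% Carriers"])
    return df.sort_values("Carriers", ascending=False,
                          kind="stable").reset_index(drop=True)
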
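"""Signature projection: per-sample pathway-activity scores.

The score of signature k in sample i is the weighted inner product

    s[k, i] = sum_g  pi[g] * (beta[g] / sigma2[g]) * x~[g, i]

over the signature probes present in the cohort, where ``x~`` is the
cohort expression centered per probe at its cohort mean (default; without
centering the score carries an arbitrary probe-mean offset).  The
precision weight ``beta / sigma2`` is the default; ``beta / sigma`` is
available via ``weight="scale"``.  Probes absent from the cohort are
dropped with a logged count rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .signature import SignatureModel

__all__ = ["ScoreVector", "project_signature", "score_correlation"]

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    """Per-sample signature-activity scores plus projection provenance."""

    label: str
    scores: pd.Series
    centering: pd.Series | None
    probes_used: list = field(default_factory=list)
    n_dropped: int = 0
    weight: str = "precision"

    def __len__(self) -> int:
        return len(self.scores)


def project_signature(
    model: SignatureModel,
    cohort: pd.DataFrame,
    center: bool = True,
    weight: str = "precision",
) -> ScoreVector:
    """Project a signature onto a cohort expression matrix.

    Parameters
    ----------
    model:
        Fitted signature supplying per-probe (pi, beta, sigma2).
    cohort:
        Log2 expression, probes x samples.  Probes are matched by id;
        signature probes missing from the cohort are dropped.
    center:
        Center each shared probe at its cohort mean before weighting
        (default on).
    weight:
        ``"precision"`` for beta/sigma2 (default) or ``"scale"`` for
        beta/sigma.
    """
    if weight not in ("precision", "scale"):
        raise ValidationError(f"unknown weight form {weight!r}")
    if len(model) == 0:
        raise ValidationError("signature model is empty")
    shared = model.table.index.intersection(cohort.index)
    n_dropped = len(model) - len(shared)
    if len(shared) == 0:
        raise ValidationError("no signature probes present in the cohort")
    if n_dropped:
        logger.info(
            "projection %s: %d of %d signature probes present in cohort "
            "(%d dropped)",
            model.label, len(shared), len(model), n_dropped,
        )
    logger.info(
        "projection %s: weight=%s centering=%s", model.label, weight,
        "on" if center else "off",
    )
    sub = model.table.loc[shared]
    denom = sub["sigma2"] if weight == "precision" else np.sqrt(sub["sigma2"])
    w = (sub["pi"] * sub["beta"] / denom).to_numpy()
    x = cohort.loc[shared]
    centering = None
    if center:
        centering = x.mean(axis=1)
        x = x.sub(centering, axis=0)
    scores = pd.Series(w @ x.to_numpy(), index=cohort.columns, name="score")
    return ScoreVector(
        label=model.label,
        scores=scores,
        centering=centering,
        probes_used=list(shared),
        n_dropped=n_dropped,
        weight=weight,
    )


def score_correlation(a, b) -> tuple[float, float]:
    """Pearson R between two score vectors with its two-sided p-value."""
    a = np.asarray(getattr(a, "scores", a), dtype=float)
    b = np.asarray(getattr(b, "scores", b), dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"length mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    if a.size < 3:
        raise ValidationError("need at least 3 paired values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
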
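"""Risk-estimate-distance (RED) core: window targets, cosine distance, loss.

A patient's survival state in time window i is a 2-D vector
``Y_i = (alpha * E_i, t_i)`` — a dimensionless risk component (``alpha``
weights death against follow-up time) and a time component in months.  RED is
the cosine distance between two such vectors:

    RED(A, B) = 1 - (A . B) / (|A| |B|)

A death is a vector tilted off the time axis by the risk weight; the earlier
the death, the larger the angle to the pure-survival direction ``(0, t)``, so
RED is larger for earlier deaths.  Training minimizes the mean cosine
distance between target and estimated vectors over the elements still under
observation (the cosine-proximity loss).

Windows are left-open right-closed intervals ``((i-1)m, i*m]``, so an event
exactly on a boundary belongs to the earlier window; there are
``W = floor(horizon / m)`` windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AT_RISK",
    "DEAD",
    "CENSORED_OUT",
    "WindowTargets",
    "build_window_targets",
    "red_distance",
    "cosine_loss",
    "cosine_loss_grad",
]

AT_RISK, DEAD, CENSORED_OUT = 0, 1, 2

NORM_FLOOR = 1e-8  # guards degenerate (near-zero) estimate vectors


@dataclass(frozen=True)
class WindowTargets:
    """Per patient (rows), per window (columns):

    status: AT_RISK (0), DEAD (1) or CENSORED_OUT (2).
    E: cumulative death indicator — 0 while at risk, 1 from the death window on.
    t: last observed time — the window boundary while at risk, frozen at the
       death/censoring time afterwards.
    boundaries: window end times ``i*m`` (months).
    """

    status: np.ndarray
    E: np.ndarray
    t: np.ndarray
    boundaries: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.status.shape[1]

    def target_vectors(self, alpha: float) -> np.ndarray:
        """(n, W, 2) array of (alpha * E_i, t_i) target vectors."""
        return np.stack([alpha * self.E, self.t], axis=-1)

    def loss_mask(self) -> np.ndarray:
        """True where the element contributes to the loss (not censored-out)."""
        return self.status != CENSORED_OUT

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (patient, window, status, E, t) for inspection."""
        n, w = self.status.shape
        return pd.DataFrame(
            {
                "patient": np.repeat(np.arange(n), w),
                "window": np.tile(np.arange(1, w + 1), n),
                "status": self.status.ravel(),
                "E": self.E.ravel(),
                "t": self.t.ravel(),
            }
        )


def build_window_targets(
    time_months: np.ndarray, event: np.ndarray, m: float, horizon: float
) -> WindowTargets:
    """Roll (time, event) outcomes out over ``W = floor(horizon/m)`` windows.

    For window i with end boundary ``b_i = i*m``:
      * death at ``t <= b_i``    -> DEAD, E_i = 1, t_i = death time (frozen);
      * still observed beyond b_i -> AT_RISK, E_i = 0, t_i = b_i;
      * censored at ``t <= b_i`` -> CENSORED_OUT with t_i frozen at the
        censoring time; excluded from the loss from that window on.
    """
    time_months = np.asarray(time_months, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time_months <= 0):
        raise ValueError("follow-up times must be positive")
    if m <= 0:
        raise ValueError("window length m must be positive")
    if horizon < m:
        raise ValueError("horizon must cover at least one window")

    n_windows = int(np.floor(horizon / m + 1e-9))
    boundaries = float(m) * np.arange(1, n_windows + 1, dtype=float)

    t_col = time_months[:, None]
    passed = t_col <= boundaries[None, :]  # event/censor time inside window i or earlier
    dead = passed & (event[:, None] == 1)
    censored = passed & (event[:, None] == 0)

    status = np.full((len(time_months), n_windows), AT_RISK, dtype=np.int8)
    status[dead] = DEAD
    status[censored] = CENSORED_OUT

    E = dead.astype(float)
    t = np.broadcast_to(boundaries, status.shape).copy()
    frozen = dead | censored
    t[frozen] = np.broadcast_to(t_col, status.shape)[frozen]
    return WindowTargets(status=status, E=E, t=t, boundaries=boundaries)


def red_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray | float:
    """Cosine distance ``1 - A.B/(|A||B|)`` between survival vectors.

    Accepts single vectors of shape (2,) or batches (..., 2).  Symmetric,
    scale-invariant, 0 for parallel and 1 for orthogonal vectors; undefined
    (raises) for zero-norm input.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na = np.linalg.norm(A, axis=-1)
    nb = np.linalg.norm(B, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("RED is undefined for a zero-norm survival vector")
    out = np.clip(1.0 - np.sum(A * B, axis=-1) / (na * nb), 0.0, 2.0)
    return float(out) if out.ndim == 0 else out


def _masked_cosine_terms(targets, estimates, mask):
    targets = np.asarray(targets, dtype=float).reshape(-1, 2)
    estimates = np.asarray(estimates, dtype=float).reshape(-1, 2)
    mask = np.asarray(mask, dtype=bool).reshape(-1)
    if targets.shape != estimates.shape or len(mask) != len(targets):
        raise ValueError("targets, estimates and mask must align")
    if not mask.any():
        raise ValueError("cosine loss over an empty mask is undefined")
    nt = np.linalg.norm(targets, axis=1)
    if np.any(nt[mask] == 0):
        raise ValueError("masked-in target with zero norm")
    ne = np.maximum(np.linalg.norm(estimates, axis=1), NORM_FLOOR)
    return targets, estimates, mask, nt, ne


def cosine_loss(targets: np.ndarray, estimates: np.ndarray, mask: np.ndarray) -> float:
    """Mean ``1 - cos`` between target and estimate vectors over masked-in
    elements; censored-out elements contribute nothing."""
    targets, estimates, mask, nt, ne = _masked_cosine_terms(targets, estimates, mask)
    cos = np.sum(targets * estimates, axis=1) / (nt * ne)
    return float(np.mean(1.0 - cos[mask]))


def cosine_loss_grad(targets: np.ndarray, estimates: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`cosine_loss` w.r.t. the estimates.

    d/db [1 - a.b/(|a||b|)] = -a/(|a||b|) + (a.b) b / (|a| |b|^3), averaged
    over the masked-in count; zero rows for masked-out elements.  The norm
    floor makes this a subgradient for degenerate near-zero estimates.
    """
    shape = np.asarray(estimates, dtype=float).shape
    targets, estimates, mask, nt, ne = _masked_cosine_terms(targets, estimates, mask)
    dot = np.sum(targets * estimates, axis=1)
    grad = -targets / (nt * ne)[:, None] + (dot / (nt * ne**3))[:, None] * estimates
    grad[~mask] = 0.0
    return (grad / mask.sum()).reshape(shape)
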
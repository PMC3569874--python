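"""Reference-panel imputation by a haploid Li-Stephens hidden Markov model,
with IMPUTE-style genotype posteriors and the info-score quality filter.

Each target haplotype (pre-phased; the simulator knows the true phase, which
mirrors the use of sample pre-phasing with real data) is modelled as a mosaic
of the K panel haplotypes.  Switches between copied haplotypes occur between
adjacent sites with probability rho_j = 1 - exp(-4 Ne r d_j / K) for
inter-site distance d_j; at a typed (scaffold) site the observed allele
matches the copied haplotype with probability 1 - lambda_LS, where
lambda_LS = theta~ / (2 (theta~ + K)) and theta~ = 1 / sum_{k=1}^{K-1} 1/k
(Watterson-style population mutation estimate).  Untyped sites emit nothing;
their allele posterior is the state-posterior-weighted panel allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LSParams:
    """Li-Stephens switch and mismatch parameters for a K-haplotype panel."""

    n_states: int
    rho: np.ndarray      # switch probability per inter-site interval, (V-1,)
    mismatch: float      # lambda_LS, per-site emission error

    @classmethod
    def from_panel(
        cls, n_states: int, positions: np.ndarray,
        ne: float = 10_000.0, rec: float = 1e-8,
    ) -> "LSParams":
        if n_states < 1:
            raise ValueError("reference panel is empty")
        d = np.diff(np.asarray(positions, dtype=float))
        rho = 1.0 - np.exp(-4.0 * ne * rec * d / n_states)
        # harmonic-number theta; the K=1 panel falls back to theta~ = 1
        denom = np.sum(1.0 / np.arange(1, max(n_states, 2)))
        theta = 1.0 / denom
        mismatch = theta / (2.0 * (theta + n_states))
        return cls(n_states=n_states, rho=rho, mismatch=mismatch)


def _emission(panel_col, targets_col, obs_col, lam):
    """(M, K) emission probabilities at one scaffold site."""
    match = targets_col[:, None] == panel_col[None, :]
    e = np.where(match, 1.0 - lam, lam)
    return np.where(obs_col[:, None], e, 1.0)


def ls_posteriors_batch(
    panel: np.ndarray,
    params: LSParams,
    targets: np.ndarray,
    target_obs: np.ndarray,
    scaffold_cols: np.ndarray,
    out_cols: np.ndarray,
    collapse_states: bool = True,
) -> np.ndarray:
    """Forward-backward allele-1 posteriors for a batch of target haplotypes.

    Parameters
    ----------
    panel : (K, V) 0/1 matrix of phased reference haplotypes at all sites.
    targets : (M, S) observed target alleles at the scaffold sites.
    target_obs : (M, S) mask; False marks a missing scaffold genotype, which
        contributes no emission for that target.
    scaffold_cols : indices into the V panel sites that are typed.
    out_cols : sorted site indices at which posteriors are returned.
    collapse_states : merge identical panel haplotypes into one copying
        state with multiplicity weight; exact (same posteriors as the
        uncollapsed chain) and faster on panels with repeated haplotypes.

    Returns an (M, len(out_cols)) matrix of P(allele = 1).
    """
    K_full, V = panel.shape
    if K_full == 0:
        raise ValueError("reference panel is empty")
    if collapse_states:
        panel_u, counts = np.unique(panel, axis=0, return_counts=True)
        pi = counts / K_full  # stationary copying weights
    else:
        panel_u = panel
        pi = np.full(K_full, 1.0 / K_full)
    M = targets.shape[0]
    lam = params.mismatch
    rho = params.rho
    col_to_s = np.full(V, -1, dtype=int)
    col_to_s[scaffold_cols] = np.arange(len(scaffold_cols))
    out_cols = np.asarray(out_cols, dtype=int)
    out_pos = {int(c): i for i, c in enumerate(out_cols)}
    panel_f = panel_u.astype(np.float32)
    pi = pi.astype(np.float32)

    # forward pass, storing the (scaled) filtered distribution at out_cols
    F = np.broadcast_to(pi, (M, len(pi))).astype(np.float32).copy()
    f_store = np.empty((len(out_cols), M, len(pi)), dtype=np.float32)
    for v in range(V):
        if v > 0:
            r = np.float32(rho[v - 1])
            F = (1 - r) * F + r * F.sum(axis=1, keepdims=True) * pi
        s = col_to_s[v]
        if s >= 0:
            F = F * _emission(panel_u[:, v], targets[:, s],
                              target_obs[:, s], lam).astype(np.float32)
        F /= F.sum(axis=1, keepdims=True)
        if v in out_pos:
            f_store[out_pos[v]] = F

    # backward pass; emit posteriors on the fly
    dosage = np.empty((M, len(out_cols)))
    B = np.ones((M, len(pi)), dtype=np.float32)
    for v in range(V - 1, -1, -1):
        if v in out_pos:
            g = f_store[out_pos[v]] * B
            g /= g.sum(axis=1, keepdims=True)
            dosage[:, out_pos[v]] = g @ panel_f[:, v]
        if v > 0:
            s = col_to_s[v]
            tmp = B
            if s >= 0:
                tmp = B * _emission(panel_u[:, v], targets[:, s],
                                    target_obs[:, s], lam).astype(np.float32)
            r = np.float32(rho[v - 1])
            B = (1 - r) * tmp + r * (tmp @ pi)[:, None]
            B /= B.sum(axis=1, keepdims=True)
    return dosage


def ls_posteriors(
    target: np.ndarray,
    panel: np.ndarray,
    params: LSParams,
    scaffold_cols: np.ndarray,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Allele-1 posterior at every panel site for one target haplotype typed
    at the scaffold sites."""
    target = np.atleast_2d(target)
    if observed is None:
        observed = np.ones_like(target, dtype=bool)
    else:
        observed = np.atleast_2d(observed)
    out = ls_posteriors_batch(
        panel, params, target, observed,
        np.asarray(scaffold_cols), np.arange(panel.shape[1]),
    )
    return out[0]


def genotype_posteriors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Combine two per-haplotype allele posteriors into genotype posterior
    triples (p0, p1, p2) over minor-allele counts; sums to 1 exactly."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    p0 = (1.0 - a) * (1.0 - b)
    p1 = a * (1.0 - b) + b * (1.0 - a)
    p2 = a * b
    return np.stack([p0, p1, p2], axis=-1)


def info_score(triples: np.ndarray, observed: np.ndarray | None = None) -> float:
    """IMPUTE-style imputation quality: the ratio of observed to
    complete-data information about the allele frequency.

    With per-sample expected dosage e_i = p1 + 2 p2 and second moment
    f_i = p1 + 4 p2, and estimated frequency theta = sum(e_i) / 2N:

        info = 1 - sum(f_i - e_i^2) / (2 N theta (1 - theta))

    clipped to [0, 1]; a monomorphic estimate (theta 0 or 1) returns 0.
    Hard calls (degenerate triples) give info = 1 exactly.
    """
    triples = np.atleast_2d(np.asarray(triples, dtype=float))
    if observed is not None:
        triples = triples[np.asarray(observed, dtype=bool)]
    if triples.shape[0] == 0:
        raise ValueError("info score needs at least one non-missing triple")
    e = triples[:, 1] + 2.0 * triples[:, 2]
    f = triples[:, 1] + 4.0 * triples[:, 2]
    n = triples.shape[0]
    theta = e.sum() / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return 0.0
    info = 1.0 - np.sum(f - e**2) / (2.0 * n * theta * (1.0 - theta))
    return float(np.clip(info, 0.0, 1.0))


def filter_imputed(
    maf: np.ndarray,
    info: np.ndarray,
    maf_threshold: float = 0.01,
    info_threshold: float = 0.4,
) -> np.ndarray:
    """Indices of variants passing the rare-variant quality filter:
    expected MAF strictly below the threshold (monomorphic dropped) and
    info score at or above the threshold (boundary inclusive)."""
    maf = np.asarray(maf, dtype=float)
    info = np.asarray(info, dtype=float)
    keep = (maf > 0.0) & (maf < maf_threshold) & (info >= info_threshold)
    return np.flatnonzero(keep)
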
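"""Independent brute-force oracles used by the test suite.

The REML oracle here deliberately shares no code with the package's
likelihood: V is assembled from explicit incidence matrices and explicit
Kronecker products over full master-block grids, and the log-likelihood uses
plain slogdet/inv linear algebra.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_LOG2PI = np.log(2.0 * np.pi)


def dense_reml_oracle(params: dict, frame: pd.DataFrame, G: np.ndarray | None, k: float | None, model: int) -> float:
    """Brute-force REML log-likelihood from a tidy trial frame.

    Observed (non-filler) plots only; genotypes ordered ungenotyped-first then
    G's order, matching the package's convention so parameter vectors mean the
    same thing on both paths.
    """
    obs = frame[frame["value"].notna() & frame["genotype_id"].notna()].reset_index(drop=True)
    y = obs["value"].to_numpy(dtype=float)
    n = len(obs)
    gen_ids = list(getattr(G, "ids", [])) if G is not None and hasattr(G, "ids") else None
    if G is not None and gen_ids is None:
        raise ValueError("pass a GenomicRelationship-like object with .ids")
    ungen = sorted(set(obs["genotype_id"]) - set(gen_ids or []))
    genotype_ids = ungen + (gen_ids or [])
    q = len(genotype_ids)
    Zu = np.zeros((n, q))
    for i, g in enumerate(obs["genotype_id"]):
        Zu[i, genotype_ids.index(g)] = 1.0
    blocks = sorted(obs["block"].unique())
    Zv = np.zeros((n, len(blocks)))
    for i, b in enumerate(obs["block"]):
        Zv[i, blocks.index(b)] = 1.0

    if model == 2 and G is not None:
        n1 = len(ungen)
        ra = params["r_a"]
        core = ra * np.asarray(G.matrix) / k + (1.0 - ra) * np.eye(len(gen_ids))
        Vu = np.zeros((q, q))
        Vu[:n1, :n1] = np.eye(n1)
        Vu[n1:, n1:] = core
        Vu *= params["sigma_u2"]
    else:
        Vu = params["sigma_u2"] * np.eye(q)

    # spatial: explicit kron over each master block's full bounding grid
    R = params["sigma_r2"] * np.eye(n)
    for mb in sorted(obs["master_block"].unique()):
        sel = np.flatnonzero((obs["master_block"] == mb).to_numpy())
        cols = obs.loc[sel, "column"].to_numpy()
        rows = obs.loc[sel, "row"].to_numpy()
        nc, nr = cols.max(), rows.max()
        ic = np.arange(1, nc + 1)
        ir = np.arange(1, nr + 1)
        Sc = params["rho_c"] ** np.abs(ic[:, None] - ic[None, :])
        Sr = params["rho_r"] ** np.abs(ir[:, None] - ir[None, :])
        full = np.kron(Sc, Sr)  # index (c-1)*nr + (r-1)
        idx = (cols - 1) * nr + (rows - 1)
        R[np.ix_(sel, sel)] += params["sigma_s2"] * full[np.ix_(idx, idx)]

    V = Zu @ Vu @ Zu.T + params["sigma_v2"] * (Zv @ Zv.T) + R
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    yPy = float(resid @ Vi @ y)
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return -0.5 * (ld_v + ld_x + yPy + (n - X.shape[1]) * _LOG2PI)


class _FakeGRM:
    def __init__(self, matrix, ids):
        self.matrix = matrix
        self.ids = ids


def random_instance(rng: np.random.Generator, with_grm: bool = True, two_mb: bool = True):
    """A small random trial frame + G + parameters for oracle comparisons (n <= 40)."""
    from clonepart.grm import GenomicRelationship

    n_geno = int(rng.integers(5, 9))
    cols, rows = int(rng.integers(3, 5)), int(rng.integers(3, 5))
    mbs = (1, 2) if two_mb else (1,)
    records = []
    gid = [f"g{i}" for i in range(n_geno)]
    for mb in mbs:
        for c in range(1, cols + 1):
            for r in range(1, rows + 1):
                if rng.random() < 0.15:
                    continue  # unobserved plot
                g = gid[int(rng.integers(0, n_geno))]
                records.append((f"t{mb}_{c}_{r}", g, "s", mb, mb, c, r, "y", float(rng.normal())))
    frame = pd.DataFrame(
        records,
        columns=["tree_id", "genotype_id", "site", "block", "master_block", "column", "row", "trait", "value"],
    )
    grm = None
    if with_grm:
        n_g = max(2, n_geno - 2)  # a couple of genotypes stay ungenotyped
        A = rng.normal(size=(n_g, 3 * n_g))
        gmat = A @ A.T / (3 * n_g)
        gmat = gmat / np.diag(gmat).mean()
        grm = GenomicRelationship(
            matrix=gmat,
            ids=sorted(rng.choice(gid, size=n_g, replace=False)),
            k=float(np.diag(gmat).mean() - gmat.mean()),
            freqs=np.asarray([]),
            freq_source="observed",
            snp_ids=[],
        )
    params = {
        "sigma_u2": float(rng.uniform(0.2, 2.0)),
        "sigma_v2": float(rng.uniform(0.0, 1.0)),
        "sigma_r2": float(rng.uniform(0.2, 2.0)),
        "sigma_s2": float(rng.uniform(0.0, 1.5)),
        "rho_c": float(rng.uniform(-0.9, 0.9)),
        "rho_r": float(rng.uniform(-0.9, 0.9)),
        "r_a": float(rng.uniform(0.0, 1.0)),
    }
    return frame, grm, params
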
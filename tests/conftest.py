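import numpy as np
import pytest

import casr_coop as cc


@pytest.fixture
def wt_protocol() -> cc.StepProtocol:
    return cc.get_preset("WT").protocol()


@pytest.fixture
def wt_cell() -> cc.CellParams:
    return cc.CellParams(onset_mM=3.0, plateau_mM=5.0, rate_fn=cc.constant_rate(1.3))


@pytest.fixture
def noiseless_wt_cell() -> cc.CellParams:
    return cc.CellParams(
        onset_mM=3.0, plateau_mM=5.0, rate_fn=cc.constant_rate(1.3), noise_sd=0.0
    )


def hill_grid_oracle(conc, response, ec50_range=(0.5, 20.0), n_range=(0.5, 8.0), size=200):
    """Brute-force global Hill fit: grid over (ec50, n) with an exact linear
    solve for (r0, rmax) at each grid point. Independent of the package's
    optimizer-based fit."""
    best = None
    ec50s = np.linspace(*ec50_range, size)
    ns = np.linspace(*n_range, size)
    for ec50 in ec50s:
        for n in ns:
            h = conc**n / (ec50**n + conc**n)
            # response = r0*(1-h) + rmax*h  -> linear least squares
            A = np.column_stack([1.0 - h, h])
            coef, rss, *_ = np.linalg.lstsq(A, response, rcond=None)
            resid = response - A @ coef
            rss = float(resid @ resid)
            if best is None or rss < best["rss"]:
                best = {"ec50": ec50, "n": n, "r0": coef[0], "rmax": coef[1], "rss": rss}
    best["ec50_step"] = ec50s[1] - ec50s[0]
    best["n_step"] = ns[1] - ns[0]
    return best


def brute_force_dccm(coords):
    """Double-loop DCCM for cross-checking the vectorised implementation."""
    f, n, _ = coords.shape
    mean = coords.mean(axis=0)
    dev = coords - mean
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(dev[t, i] @ dev[t, j] for t in range(f)) / f
            vi = sum(dev[t, i] @ dev[t, i] for t in range(f)) / f
            vj = sum(dev[t, j] @ dev[t, j] for t in range(f)) / f
            c[i, j] = num / np.sqrt(vi * vj)
    return c


def brute_force_pca(coords):
    """Explicit covariance eigendecomposition for cross-checking."""
    f = coords.shape[0]
    X = coords.reshape(f, -1)
    X = X - X.mean(axis=0)
    cov = X.T @ X / f
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]
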
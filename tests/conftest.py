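import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_shpm(X, levels, combine_mode="concat", temporal_mode="mean"):
    """Brute-force SHPM oracle: explicit loops over batch, channel, frame
    and spatial bins, kept independent of the package implementation."""
    B, C, T, H, W = X.shape
    rows = []
    for b in range(B):
        feats = []
        for (hs, ws) in levels:
            assert H % hs == 0 and W % ws == 0
            hb, wb = H // hs, W // ws
            mu = np.zeros((C, T, hb, wb))
            eta = np.zeros((C, T, hb, wb))
            for c in range(C):
                for t in range(T):
                    for i in range(hb):
                        for j in range(wb):
                            block = []
                            for h in range(hs):
                                for w in range(ws):
                                    block.append(
                                        X[b, c, t, i * hs + h, j * ws + w])
                            mu[c, t, i, j] = max(block)
                            eta[c, t, i, j] = sum(block) / len(block)
            if temporal_mode == "mean":
                mu_t, eta_t = mu.mean(axis=1), eta.mean(axis=1)
            else:
                mu_t, eta_t = mu.max(axis=1), eta.max(axis=1)
            if combine_mode == "concat":
                feats.append(np.concatenate([mu_t.ravel(), eta_t.ravel()]))
            else:
                feats.append(mu_t.ravel() + eta_t.ravel())
        rows.append(np.concatenate(feats))
    return np.stack(rows)


@pytest.fixture
def shpm_oracle():
    return naive_shpm
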
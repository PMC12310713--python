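import numpy as np
import pytest

from flaseg.attention import FlabParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_flab_params(rng: np.random.Generator, pool_kernel: int = 3,
                       hidden: int = 2, channels: int | None = None) -> FlabParams:
    """Seeded plain-array FLAB parameters (shared across channels)."""
    return FlabParams(
        pool_kernel=pool_kernel,
        feature_w1=rng.normal(size=(hidden, 2)),
        feature_b1=rng.normal(size=(hidden,)) * 0.1,
        feature_w2=rng.normal(size=(1, hidden)),
        feature_b2=rng.normal(size=(1,)) * 0.1,
        location_w=rng.normal(size=(7, 7, 2)) * 0.2,
        location_b=float(rng.normal()) * 0.1,
    )


@pytest.fixture
def flab_params(rng):
    return random_flab_params(rng)


# -- independent scalar oracles (shared by unit and acceptance tests) ------

def oracle_pooled_pair(x, k):
    """Brute-force stride-1 avg/max pooling with edge replication."""
    h, w = x.shape
    p = k // 2
    avg = np.zeros((h, w))
    mx = np.zeros((h, w))
    for y in range(h):
        for xx in range(w):
            vals = []
            for u in range(-p, p + 1):
                for v in range(-p, p + 1):
                    ys = min(max(y + u, 0), h - 1)
                    xs = min(max(xx + v, 0), w - 1)
                    vals.append(float(x[ys, xs]))
            avg[y, xx] = sum(vals) / len(vals)
            mx[y, xx] = max(vals)
    return avg, mx


def oracle_feature_weight(x, params):
    avg, mx = oracle_pooled_pair(np.asarray(x, dtype=float), params.pool_kernel)
    w1 = np.asarray(params.feature_w1, dtype=float)
    b1 = np.asarray(params.feature_b1, dtype=float)
    w2 = np.asarray(params.feature_w2, dtype=float)
    b2 = np.asarray(params.feature_b2, dtype=float)
    h, w = x.shape
    out = np.zeros((h, w))
    r = w1.shape[0]
    for y in range(h):
        for xx in range(w):
            hid = []
            for j in range(r):
                pre = w1[j, 0] * avg[y, xx] + w1[j, 1] * mx[y, xx] + b1[j]
                hid.append(max(pre, 0.0))
            out[y, xx] = sum(w2[0, j] * hid[j] for j in range(r)) + b2[0]
    return out


def oracle_location_weight(x, params):
    avg, mx = oracle_pooled_pair(np.asarray(x, dtype=float), params.pool_kernel)
    w = np.asarray(params.location_w, dtype=float)
    k = w.shape[0]
    p = k // 2
    h, ww = x.shape
    out = np.zeros((h, ww))
    for y in range(h):
        for xx in range(ww):
            s = float(np.asarray(params.location_b).reshape(-1)[0])
            for u in range(k):
                for v in range(k):
                    ys, xs = y + u - p, xx + v - p
                    if 0 <= ys < h and 0 <= xs < ww:
                        s += w[u, v, 0] * avg[ys, xs] + w[u, v, 1] * mx[ys, xs]
            out[y, xx] = s
    return out


def oracle_confusion(pred, truth):
    tp = tn = fp = fn = 0
    for p, t in zip(np.asarray(pred).ravel(), np.asarray(truth).ravel()):
        if p == 1 and t == 1:
            tp += 1
        elif p == 0 and t == 0:
            tn += 1
        elif p == 1 and t == 0:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn
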
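import numpy as np
import pytest

import wormwell as ww


@pytest.fixture(scope="session")
def config():
    return ww.PipelineConfig()


@pytest.fixture(scope="session")
def phantom():
    """One default high-contrast phantom well."""
    return ww.generate_well_phantom(ww.PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom_seg(phantom):
    return ww.segment_well(phantom.brightfield, phantom.well_mask)


def brute_force_grey_closing(image, footprint):
    """Independent grayscale closing oracle: dilation then erosion, edge-padded."""
    img = np.asarray(image, dtype=float)
    r = footprint.shape[0] // 2
    offsets = [(dy - r, dx - r) for dy, dx in zip(*np.nonzero(footprint))]

    def _apply(arr, reducer):
        padded = np.pad(arr, r, mode="edge")
        out = np.empty_like(arr)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                vals = [padded[i + r + dy, j + r + dx] for dy, dx in offsets]
                out[i, j] = reducer(vals)
        return out

    return _apply(_apply(img, max), min)


def brute_force_label(mask):
    """Independent 8-connected component labelling by flood fill."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, int)
    current = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                labels[i, j] = current
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < mask.shape[0]
                                and 0 <= xx < mask.shape[1]
                                and mask[yy, xx]
                                and labels[yy, xx] == 0
                            ):
                                labels[yy, xx] = current
                                stack.append((yy, xx))
    return labels, current


def brute_force_welch(a, b):
    """Textbook Welch statistic, Welch-Satterthwaite df and two-tailed p."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def brute_force_holm(p):
    """Step-down Holm adjustment, straight from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adj[idx] = running
    return adj


def brute_force_otsu(hist):
    """Exhaustive search over all 255 cuts for the max between-class variance."""
    h = np.asarray(hist, float)
    p = h / h.sum()
    bins = np.arange(256)
    mu = (p * bins).sum()
    var_total = (p * (bins - mu) ** 2).sum()
    best_t, best_v = 0, -1.0
    for t in range(255):
        w0 = p[: t + 1].sum()
        w1 = 1 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = (p[: t + 1] * bins[: t + 1]).sum() / w0
        mu1 = (p[t + 1 :] * bins[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t, best_v / var_total
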
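"""Independent reference implementations used as test oracles.

Everything here is written as plain scalar loops, deliberately not
sharing any code path with the package, so agreement is evidence rather
than tautology.
"""

from __future__ import annotations

import numpy as np

from sleepssm.model import HeadConfig, ModelConfig, MSCNNConfig, SSMConfig


def reference_metrics(cm: np.ndarray) -> dict:
    """Loop-based one-vs-rest metric suite on a k×k confusion matrix.

    Accuracy is trace/total; macro-F1 the mean of per-class F1;
    kappa (p_o − p_e)/(1 − p_e); Sen/Spec/Pre are per-class one-vs-rest
    ratios macro-averaged, with zero denominators contributing 0.
    All on the 0–100 scale.
    """
    cm = np.asarray(cm, dtype=np.int64)
    k = cm.shape[0]
    total = cm.sum()
    trace = sum(int(cm[i, i]) for i in range(k))
    f1s, sens, specs, pres = [], [], [], []
    for c in range(k):
        tp = int(cm[c, c])
        fn = sum(int(cm[c, j]) for j in range(k) if j != c)
        fp = sum(int(cm[i, c]) for i in range(k) if i != c)
        tn = int(total) - tp - fn - fp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
        sens.append(100.0 * rec if tp + fn > 0 else 0.0)
        specs.append(100.0 * (tn / (tn + fp)) if tn + fp > 0 else 0.0)
        pres.append(100.0 * prec if tp + fp > 0 else 0.0)
    p_o = trace / total
    p_e = sum(int(cm[c].sum()) * int(cm[:, c].sum()) for c in range(k)) / total**2
    kappa = 0.0 if p_e >= 1.0 else 100.0 * (p_o - p_e) / (1.0 - p_e)
    return {
        "acc": 100.0 * trace / total,
        "mf1": 100.0 * float(np.mean(f1s)),
        "kappa": kappa,
        "sen": float(np.mean(sens)),
        "spec": float(np.mean(specs)),
        "pre": float(np.mean(pres)),
        "per_class_precision": np.array(pres),
    }


def reference_ssm_recurrence(xs, s_mats, b_in, h0, literal=False):
    """Scalar-loop reference of the coupled state recurrence with
    attention refinement, for one batch element.

    xs: (T, M, D) normalised inputs; s_mats: (M, H, H); b_in: (D, H);
    h0: (M, H).  Returns final states (M, H).
    """
    xs = np.asarray(xs, dtype=np.float64)
    s_mats = np.asarray(s_mats, dtype=np.float64)
    b_in = np.asarray(b_in, dtype=np.float64)
    T, M, D = xs.shape
    H = b_in.shape[1]
    h_prev = [np.asarray(h0[n], dtype=np.float64).copy() for n in range(M)]
    for t in range(T):
        drive = [np.zeros(H) for _ in range(M)]
        for n in range(M):
            for j in range(H):
                drive[n][j] = sum(xs[t, n, d] * b_in[d, j] for d in range(D))
        h_pre = []
        for n in range(M):
            acc = drive[n].copy()
            for m in range(M):
                for j in range(H):
                    acc[j] += sum(h_prev[m][i] * s_mats[n][i, j]
                                  for i in range(H))
            h_pre.append(np.tanh(acc))
        if M == 1:
            h_prev = h_pre
            continue
        # scaled dot-product attention over source modality m
        alpha = np.zeros((M, M))
        for n in range(M):
            scores = [sum(h_pre[n][i] * h_pre[m][i] for i in range(H))
                      / np.sqrt(H) for m in range(M)]
            e = np.exp(scores - max(scores))
            alpha[n] = e / e.sum()
        h_new = []
        for n in range(M):
            acc = drive[n].copy()
            for m in range(M):
                hist = h_prev[n] if literal else h_prev[m]
                for j in range(H):
                    acc[j] += alpha[n, m] * sum(
                        hist[i] * s_mats[n][i, j] for i in range(H))
            h_new.append(np.tanh(acc))
        h_prev = h_new
    return np.stack(h_prev)


def tiny_model_config(dtype: str = "float64") -> ModelConfig:
    """A few-parameter configuration for finite-difference checks."""
    return ModelConfig(
        mscnn=MSCNNConfig(large_kernel=10, large_stride=8, small_kernel=6,
                          small_stride=4, filters=4, pool_size=2,
                          second_kernel=3, second_stride=1, second_filters=4),
        ssm=SSMConfig(hidden_dim=3, n_modalities=2),
        head=HeadConfig(hidden=6, dropout=0.0),
        se_reduction=2, epoch_len=120, dtype=dtype)


def small_model_config(dtype: str = "float32") -> ModelConfig:
    """Reduced-width model at full epoch length, for fast smoke training."""
    return ModelConfig(
        mscnn=MSCNNConfig(filters=8, second_filters=8),
        ssm=SSMConfig(hidden_dim=16, n_modalities=2),
        head=HeadConfig(hidden=16, dropout=0.5),
        se_reduction=4, epoch_len=3000, dtype=dtype)


def finite_difference_max_rel_err(model, x, y, samples_per_param=2,
                                  eps=1e-6, seed=0) -> float:
    """Compare autodiff gradients of the cross-entropy loss against
    central finite differences on a random subset of each parameter."""
    rng = np.random.default_rng(seed)
    yy = np.asarray(y)

    def loss_val():
        lsm = model.forward(x).log_softmax(axis=-1)
        return -lsm[np.arange(len(yy)), yy].mean()

    model.zero_grad()
    loss_val().backward()
    maxrel = 0.0
    for t in model.parameters().values():
        flat = t.data.reshape(-1)
        g = (t.grad.reshape(-1) if t.grad is not None
             else np.zeros_like(flat))
        idxs = rng.choice(flat.size, size=min(samples_per_param, flat.size),
                          replace=False)
        for i in idxs:
            old = flat[i]
            flat[i] = old + eps
            lp = loss_val().data
            flat[i] = old - eps
            lm = loss_val().data
            flat[i] = old
            fd = (lp - lm) / (2 * eps)
            rel = abs(fd - g[i]) / max(1e-8, abs(fd), abs(g[i]))
            maxrel = max(maxrel, rel)
    return maxrel
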
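"""Independent reference implementations used as test oracles.

Deliberately naive (explicit loops, no shared code with the package) so
they check the package's vectorized computations from an independent
path.
"""

import numpy as np


def naive_anchor(emb, labels, c):
    rows = [e for e, y in zip(emb, labels) if y == c]
    return np.mean(rows, axis=0)


def naive_patient_means(emb, labels, pids, c):
    means = {}
    for p in sorted(set(int(q) for q, y in zip(pids, labels) if y == c)):
        rows = [e for e, y, q in zip(emb, labels, pids) if y == c and q == p]
        means[p] = np.mean(rows, axis=0)
    return means


def naive_clustering_loss(emb, labels, pids, alpha):
    total = 0.0
    for c in sorted(set(int(y) for y in labels)):
        a = naive_anchor(emb, labels, c)
        for p, m in naive_patient_means(emb, labels, pids, c).items():
            d2 = 0.0
            for k in range(len(a)):
                d2 += (a[k] - m[k]) ** 2
            total += alpha * d2
    return total


def naive_separation_loss(emb, labels, pids, beta):
    classes = sorted(set(int(y) for y in labels))
    total = 0.0
    for c in classes:
        a = naive_anchor(emb, labels, c)
        for c_neg in classes:
            if c_neg == c:
                continue
            for p, m in naive_patient_means(emb, labels, pids, c_neg).items():
                d2 = 0.0
                for k in range(len(a)):
                    d2 += (a[k] - m[k]) ** 2
                total += beta[(c, c_neg)] * d2
    return total


def naive_adaptive_beta(emb, labels, epsilon=1e-8):
    classes = sorted(set(int(y) for y in labels))
    anchors = {c: naive_anchor(emb, labels, c) for c in classes}
    beta = {}
    for c in classes:
        raw = {}
        for c_neg in classes:
            if c_neg == c:
                continue
            d2 = sum((anchors[c][k] - anchors[c_neg][k]) ** 2
                     for k in range(len(anchors[c])))
            raw[c_neg] = 1.0 / max(d2, epsilon)
        z = sum(raw.values())
        for c_neg, b in raw.items():
            beta[(c, c_neg)] = b / z
    return beta


def brute_silhouette(X, labels):
    """Per-sample silhouette via explicit pairwise loops."""
    n = len(X)
    labels = list(labels)
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            s[i] = 0.0
            continue
        a = np.mean([np.linalg.norm(np.asarray(X[i]) - np.asarray(X[j]))
                     for j in same])
        b = np.inf
        for c in set(labels):
            if c == labels[i]:
                continue
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean([np.linalg.norm(np.asarray(X[i]) - np.asarray(X[j]))
                                for j in other]))
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


def random_anchor_batch(rng, max_classes=3, dim=4):
    """A random small batch varying classes, patients and pixels per patient."""
    n_classes = rng.integers(2, max_classes + 1)
    emb, labels, pids = [], [], []
    pid = 0
    for c in range(n_classes):
        for _ in range(rng.integers(1, 4)):       # patients per class
            for _ in range(rng.integers(1, 5)):   # pixels per patient
                emb.append(rng.normal(size=dim))
                labels.append(c)
                pids.append(pid)
            pid += 1
    return np.array(emb), np.array(labels), np.array(pids)
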
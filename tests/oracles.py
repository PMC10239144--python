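"""Independent brute-force oracles used to check the implementation.

Everything here is written as plainly as possible — path enumeration,
explicit loops, explicit matrix inversion — and deliberately shares no code
with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# --- semantic similarity -----------------------------------------------------


def brute_wang_contributions(dag, disease):
    """Contribution of each ancestor = max over directed paths to the disease
    of 0.5 ** path_length, found by exhaustive simple-path enumeration."""
    import networkx as nx

    contribs = {disease: 1.0}
    for node in dag.nodes:
        if node == disease:
            continue
        best = 0.0
        for path in nx.all_simple_paths(dag, node, disease):
            best = max(best, 0.5 ** (len(path) - 1))
        contribs[node] = best
    return contribs


def brute_xuan_contributions(forest_dags, disease):
    """-log(#DAGs containing term / #diseases), counted by explicit loops."""
    n = len(forest_dags)
    contribs = {}
    for term in forest_dags[disease].nodes:
        count = sum(1 for g in forest_dags.values() if term in g)
        contribs[term] = -np.log(count / n)
    return contribs


def brute_semantic_matrix(contribs_by_disease, names):
    """Pairwise similarity by explicit intersection loops."""
    n = len(names)
    out = np.zeros((n, n))
    for a, b in itertools.product(range(n), repeat=2):
        ca, cb = contribs_by_disease[names[a]], contribs_by_disease[names[b]]
        dva, dvb = sum(ca.values()), sum(cb.values())
        if dva + dvb == 0:
            out[a, b] = 0.0
            continue
        total = 0.0
        for term in ca:
            if term in cb:
                total += ca[term] + cb[term]
        out[a, b] = total / (dva + dvb)
    for i in range(n):
        if sum(contribs_by_disease[names[i]].values()) > 0:
            out[i, i] = 1.0
    return out


# --- functional similarity ---------------------------------------------------


def brute_functional_similarity(dd, md_values):
    """Best-match average similarity by explicit loops; NaN when undefined."""
    nm = md_values.shape[0]
    out = np.full((nm, nm), np.nan)
    sets = [list(np.flatnonzero(md_values[i])) for i in range(nm)]
    for i, j in itertools.product(range(nm), repeat=2):
        di, dj = sets[i], sets[j]
        if not di or not dj:
            continue
        total = 0.0
        for t in di:
            total += max(dd[t, u] for u in dj)
        for t in dj:
            total += max(dd[t, u] for u in di)
        out[i, j] = total / (len(di) + len(dj))
    return out


# --- Gaussian kernel ---------------------------------------------------------


def brute_gaussian_kernel(profiles):
    """exp(-gamma * squared distance) with gamma = 1 / mean squared norm."""
    n = profiles.shape[0]
    gamma = 1.0 / np.mean([np.dot(p, p) for p in profiles])
    out = np.empty((n, n))
    for i, j in itertools.product(range(n), repeat=2):
        d = profiles[i] - profiles[j]
        out[i, j] = np.exp(-gamma * np.dot(d, d))
    return out


# --- KATZ --------------------------------------------------------------------


def katz_series(a, beta, k):
    """Truncated walk series  sum_{l=1..k} beta^l A^l  by repeated products."""
    out = np.zeros_like(a, dtype=float)
    term = np.eye(a.shape[0])
    for _ in range(k):
        term = beta * (term @ a)
        out += term
    return out


# --- ROC / AUC ---------------------------------------------------------------


def mann_whitney_auc(pos_scores, neg_scores):
    """U statistic / (n_pos * n_neg) with ties credited 0.5, by double loop."""
    u = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u / (len(pos_scores) * len(neg_scores))


# --- end-to-end reference pipeline ------------------------------------------


def reference_scores(md_values, forest_dags, disease_names, alpha):
    """Straight-line re-derivation of the full prediction pipeline.

    Uses the brute-force pieces above, explicit matrix inversion and loop
    projections; serves as the end-to-end oracle for micro-fixtures.
    """
    nm, nd = md_values.shape
    has_dag = [d in forest_dags for d in disease_names]

    wang = {}
    xuan = {}
    for d, present in zip(disease_names, has_dag):
        if present:
            wang[d] = brute_wang_contributions(forest_dags[d], d)
            xuan[d] = brute_xuan_contributions(forest_dags, d)
    dag_names = [d for d, p in zip(disease_names, has_dag) if p]
    dd1 = np.zeros((nd, nd))
    dd2 = np.zeros((nd, nd))
    if dag_names:
        sub1 = brute_semantic_matrix(wang, dag_names)
        sub2 = brute_semantic_matrix(xuan, dag_names)
        idx = [disease_names.index(d) for d in dag_names]
        for a, ia in enumerate(idx):
            for b, ib in enumerate(idx):
                dd1[ia, ib] = sub1[a, b]
                dd2[ia, ib] = sub2[a, b]

    gd = brute_gaussian_kernel(md_values.T.astype(float))
    gm = brute_gaussian_kernel(md_values.astype(float))
    mm1 = brute_functional_similarity(dd1, md_values)
    mm2 = brute_functional_similarity(dd2, md_values)

    id_ = np.empty((nd, nd))
    for i, j in itertools.product(range(nd), repeat=2):
        if has_dag[i] and has_dag[j]:
            id_[i, j] = (dd1[i, j] + dd2[i, j]) / 2
        else:
            id_[i, j] = gd[i, j]
    im = np.empty((nm, nm))
    for i, j in itertools.product(range(nm), repeat=2):
        if np.isnan(mm1[i, j]):
            im[i, j] = gm[i, j]
        else:
            im[i, j] = (mm1[i, j] + mm2[i, j]) / 2
    np.fill_diagonal(id_, 1.0)
    np.fill_diagonal(im, 1.0)

    a = np.zeros((nm + nd, nm + nd))
    a[:nm, :nm] = im
    a[:nm, nm:] = md_values
    a[nm:, :nm] = md_values.T
    a[nm:, nm:] = id_
    eig_a = max(np.linalg.eigvalsh(a))
    beta = alpha / eig_a
    s = np.linalg.inv(np.eye(nm + nd) - beta * a) - np.eye(nm + nd)
    est = s[:nm, nm:]

    pm = np.zeros((nm, nd))
    pd_ = np.zeros((nm, nd))
    for i, j in itertools.product(range(nm), range(nd)):
        cn = np.sqrt(np.dot(est[:, j], est[:, j]))
        if cn > 0:
            pm[i, j] = np.dot(im[i, :], est[:, j]) / cn
        rn = np.sqrt(np.dot(est[i, :], est[i, :]))
        if rn > 0:
            pd_[i, j] = np.dot(est[i, :], id_[:, j]) / rn
    return (pm + pd_) / 2
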
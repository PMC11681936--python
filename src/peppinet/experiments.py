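"""Reference experiments on synthetic data.

Each function here runs one self-contained study of the pipeline at small
scale — architecture shape arithmetic, oracle agreement of the graph
convolution and the ranking metrics, planted-signal recovery, branch
dissociation, repeated-CV stability, and the consistency filter — and
returns plain numbers.  The test suite asserts on them; the acceptance
script reports them.

Problem sizes are chosen for a single CPU: embeddings of dimension 16,
chains of 8-40 residues, 200 labelled pairs, 25 training epochs.  The
architecture (stage structure, K, BN-ReLU head) is identical to the
full-scale configuration.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .fixtures import FixtureSpec, make_planted_dataset
from .fusion_head import fuse
from .graph_encoder import TagConvParams, tag_conv
from .model import PepPIModel
from .seq_encoder import stage_widths
from .structures_io import check_consistency, normalize_adjacency
from .train_eval import (
    PairDataset,
    _encode_dataset,
    _mean_report,
    chain_disjoint_split,
    compute_metrics,
    cross_validate,
    train,
)

__all__ = [
    "shape_summary",
    "graph_conv_oracle",
    "normalization_oracle",
    "metrics_oracle",
    "fusion_limits",
    "planted_recovery",
    "branch_dissociation",
    "repeated_cv_stability",
    "filter_behavior",
]


def shape_summary(seed: int = 0) -> dict:
    """Measure actual tensor widths on a 1200-length input, 128 channels."""
    cfg = RunConfig(embedding_dim=16, max_length=1200, conv_channels=128,
                    tag_channels=128, feature_dim=128, seed=seed)
    model = PepPIModel(cfg)
    from .autodiff import Tensor, conv1d, maxpool1d

    rng = np.random.default_rng(np.random.PCG64(seed))
    h = Tensor(rng.normal(size=(1, 1200, 16)))
    widths = []
    for w, b in zip(model.seq_encoder.weights, model.seq_encoder.biases):
        h = conv1d(h, w, b).relu()
        widths.append(h.shape[1])
        h = maxpool1d(h, 3)
        widths.append(h.shape[1])
    seq_feat = h.max(axis=1)
    # structure branch on a 40-residue chain
    from .embeddings import SyntheticEmbedder
    from .fixtures import make_chain

    chain = make_chain("ACDEFGHIKLMNPQRSTVWY" * 2, "random_walk", seed=seed)
    emb = SyntheticEmbedder(16, seed).embed(chain.sequence)
    enc = model.encode_chain(chain, emb)
    struct_feat = model.graph_encoder.forward_one(enc.power_features)
    return {
        "widths": widths,
        "first_conv_width": widths[0],
        "first_pool_width": widths[1],
        "closed_form_widths": stage_widths(1200),
        "seq_feature_dim": int(seq_feat.shape[1]),
        "struct_feature_dim": int(struct_feat.shape[1]),
    }


def graph_conv_oracle(seed: int = 0, n_graphs: int = 100) -> dict:
    """Max |tag_conv - dense polynomial oracle| over random graphs; locality."""
    g = np.random.default_rng(np.random.PCG64(seed))
    worst = 0.0
    for _ in range(n_graphs):
        n = int(g.integers(2, 11))
        k = int(g.integers(1, 5))
        c_in, c_out = int(g.integers(1, 4)), int(g.integers(1, 5))
        adj = np.triu((g.random((n, n)) < 0.5).astype(int), 1)
        a = normalize_adjacency(adj + adj.T)
        params = TagConvParams(g.normal(size=(c_in, c_out, k + 1)),
                               g.normal(size=c_out))
        x = g.normal(size=(n, c_in))
        dense = np.zeros((n, c_out))
        for f in range(c_out):
            for c in range(c_in):
                for kk in range(k + 1):
                    dense[:, f] += params.coefficients[c, f, kk] * (
                        np.linalg.matrix_power(a, kk) @ x[:, c]
                    )
            dense[:, f] += params.bias[f]
        worst = max(worst,
                    float(np.abs(tag_conv(a, x, params)
                                 - np.maximum(dense, 0)).max()))
    # K-hop locality on a 7-node path: node 1 is 6 hops from node 7
    adj = np.zeros((7, 7), dtype=int)
    for i in range(6):
        adj[i, i + 1] = adj[i + 1, i] = 1
    a = normalize_adjacency(adj)
    params = TagConvParams(g.normal(size=(1, 2, 4)), g.normal(size=2))
    x = g.normal(size=(7, 1))
    x2 = x.copy()
    x2[6, 0] += 5.0
    leak = float(np.abs(tag_conv(a, x, params)[0]
                        - tag_conv(a, x2, params)[0]).max())
    return {"max_abs_dev": worst, "n_graphs": n_graphs, "locality_leak": leak}


def normalization_oracle(seed: int = 0, n_graphs: int = 50) -> dict:
    """Max deviation of the self-looped normalization from the closed form."""
    g = np.random.default_rng(np.random.PCG64(seed))
    worst = 0.0
    asym = 0.0
    for _ in range(n_graphs):
        n = int(g.integers(1, 13))
        adj = np.triu((g.random((n, n)) < 0.4).astype(int), 1)
        adj = adj + adj.T
        out = normalize_adjacency(adj)
        a_hat = adj + np.eye(n)
        d_half = np.diag(1 / np.sqrt(a_hat.sum(axis=1)))
        worst = max(worst, float(np.abs(out - d_half @ a_hat @ d_half).max()))
        asym = max(asym, float(np.abs(out - out.T).max()))
    edgeless = float(np.abs(normalize_adjacency(np.zeros((5, 5)))
                            - np.eye(5)).max())
    return {"max_abs_dev": worst, "max_asymmetry": asym,
            "edgeless_identity_dev": edgeless, "n_graphs": n_graphs}


def metrics_oracle(seed: int = 0, n_instances: int = 1000) -> dict:
    """Fixed-confusion metric values plus AUC vs the rank-statistic oracle."""
    labels = [1, 1, 0, 0, 0, 0]
    scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.05]  # TP=2 FP=1 TN=3 FN=0
    rep = compute_metrics(labels, scores)
    g = np.random.default_rng(np.random.PCG64(seed))
    worst = 0.0
    checked = 0
    while checked < n_instances:
        n = int(g.integers(4, 60))
        y = g.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        s = np.round(g.random(n), 2)  # coarse grid to exercise tie handling
        pos, neg = s[y == 1], s[y == 0]
        comp = (pos[:, None] > neg[None, :]).sum() \
            + 0.5 * (pos[:, None] == neg[None, :]).sum()
        oracle = comp / (len(pos) * len(neg))
        got = compute_metrics(y, s).auc
        worst = max(worst, abs(got - oracle))
        checked += 1
    # the two AUC aggregation conventions on a constructed two-fold example
    fold1 = ([0, 1], [0.1, 0.9])
    fold2 = ([0, 1], [0.5, 0.5])
    mean_auc = _mean_report(
        [compute_metrics(*fold1), compute_metrics(*fold2)]).auc
    pooled_auc = compute_metrics(fold1[0] + fold2[0], fold1[1] + fold2[1]).auc
    return {
        "acc": rep.acc, "prec": rep.prec, "recall": rep.recall,
        "spec": rep.spec, "f1": rep.f1,
        "auc_rank_oracle_max_abs_dev": float(worst),
        "n_instances": n_instances,
        "convention_fold_mean_auc": mean_auc,
        "convention_pooled_auc": pooled_auc,
    }


def fusion_limits(seed: int = 0) -> dict:
    """Bitwise agreement of the w=0 / w=1 fusion limits."""
    g = np.random.default_rng(np.random.PCG64(seed))
    fg, fs = g.normal(size=128), g.normal(size=128)
    dev0 = float(np.abs(fuse(fg, fs, 0.0).values - fg).max())
    dev1 = float(np.abs(fuse(fg, fs, 1.0).values - fs).max())
    exact = (np.array_equal(fuse(fg, fs, 0.0).values, fg)
             and np.array_equal(fuse(fg, fs, 1.0).values, fs))
    return {"w0_max_abs_dev": dev0, "w1_max_abs_dev": dev1,
            "bitwise_exact": bool(exact)}


def planted_recovery(seed: int = 1, epochs: int = 25) -> dict:
    """Train and 5-fold cross-validate on the planted-motif dataset."""
    dataset = make_planted_dataset(FixtureSpec(seed=seed))
    cfg = RunConfig.test_profile(seed=seed, epochs=epochs)
    _, history = train(dataset, cfg)
    cv = cross_validate(dataset, cfg, k=5, seed=seed)
    return {
        "n_pairs": len(dataset),
        "train_accuracy": history["train_accuracy"],
        "cv_accuracy_pooled": cv["pooled"].acc,
        "cv_auc_pooled": cv["pooled"].auc,
        "cv_auc_fold_mean": cv["per_fold_mean"].auc,
        "cv_f1_pooled": cv["pooled"].f1,
    }


def _heldout_accuracy(dataset: PairDataset, cfg: RunConfig,
                      split_seed: int) -> float:
    tr, tst = chain_disjoint_split(dataset, 0.3, seed=split_seed)
    model, _ = train(tr, cfg)
    scores = model.predict_scores(_encode_dataset(model, tst))
    return float(np.mean((scores >= cfg.threshold) == (tst.labels() == 1)))


def branch_dissociation(seed: int = 1, epochs: int = 25) -> dict:
    """Held-out accuracy of each branch alone on each planted rule.

    Chains are split disjointly between train and test so success requires
    the planted rule itself, not memorized chain fingerprints.  The graph
    branch runs on rule-neutral node features (one-hot composition for the
    motif rule, node degree for the geometry rule) so each branch sees only
    its own signal channel.
    """
    out = {}
    emb_ds = make_planted_dataset(FixtureSpec(seed=seed + 1,
                                              planted_rule="embedding"))
    struct_ds = make_planted_dataset(FixtureSpec(seed=seed + 2,
                                                 planted_rule="structure"))
    for rule, ds, feats in (("embedding", emb_ds, "onehot"),
                            ("structure", struct_ds, "degree")):
        for w in (0.0, 1.0):
            cfg = RunConfig.test_profile(seed=seed + 3, epochs=epochs,
                                         fusion_weight=w,
                                         node_feature_source=feats)
            out[f"{rule}_rule_w{int(w)}_heldout_acc"] = _heldout_accuracy(
                ds, cfg, split_seed=seed + 4)
    return out


def repeated_cv_stability(seed: int = 1, n_repeats: int = 4,
                          epochs: int = 25) -> dict:
    """SD of each pooled metric across repeated 5-fold CVs (distinct seeds)."""
    dataset = make_planted_dataset(FixtureSpec(seed=seed))
    cfg = RunConfig.test_profile(seed=seed, epochs=epochs)
    names = ("acc", "prec", "recall", "spec", "f1", "auc", "auprc")
    values = {m: [] for m in names}
    for r in range(n_repeats):
        rep = cross_validate(dataset, cfg, k=5, seed=seed + 100 + r)["pooled"]
        for m in names:
            values[m].append(getattr(rep, m))
    sds = {f"sd_{m}": float(np.std(v)) for m, v in values.items()}
    sds["max_sd"] = max(sds.values())
    sds["n_repeats"] = n_repeats
    sds["mean_acc"] = float(np.mean(values["acc"]))
    return sds


def filter_behavior(seed: int = 1) -> dict:
    """Corrupt one chain's structure; count pairs the filter must drop."""
    from .fixtures import _pdb_from_chain, corrupt_pdb
    from .structures_io import parse_chain

    dataset = make_planted_dataset(FixtureSpec(seed=seed, n_pairs=60))
    victim = dataset.pairs[0].receptor_id
    chain = dataset.chains[victim]
    broken = parse_chain(corrupt_pdb(_pdb_from_chain(chain)), chain.chain_id)
    passes = {
        cid: check_consistency(
            broken if cid == victim else dataset.chains[cid],
            dataset.embeddings[cid],
        )
        for cid in dataset.chains
    }
    kept = [p for p in dataset.pairs
            if passes[p.receptor_id] and passes[p.peptide_id]]
    expected_kept = [p for p in dataset.pairs
                     if victim not in (p.receptor_id, p.peptide_id)]
    return {
        "n_pairs": len(dataset.pairs),
        "n_dropped": len(dataset.pairs) - len(kept),
        "n_expected_dropped": len(dataset.pairs) - len(expected_kept),
        "n_chains_failing": sum(1 for ok in passes.values() if not ok),
    }
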
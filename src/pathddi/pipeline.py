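"""Stage orchestration: simulate -> preprocess -> embed -> train -> explain.

Each stage reads and writes plain files in a working directory, so synthetic
and real runs follow the same path and every run is auditable.  All stages
derive their randomness from the single config seed; identical configs
produce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import io, kg as kgmod, tokenizer
from .config import RunConfig
from .interpret import (partner_group_distributions, screen_pathways,
                        distribution_summary, CENTRALITY_ORDER,
                        merge_subgraphs)
from .kg_embedding import build_matrix
from .model import DDIModel, DrugBatch, VARIANT_BLOCKS
from .molgraph import parse_to_adjacency
from .synthetic import SyntheticSpec, gen_ddi, gen_embeddings, gen_kg, gen_smiles
from .training import evaluate, make_folds, train_fold

_VARIANTS_WITHOUT_SP = {"kg-rw", "transformer+kg-rw"}


def _fname(drug_id: str) -> str:
    return drug_id.replace("::", "__").replace("/", "_") + ".json"


def _log(messages: list[str], text: str, verbose: bool) -> None:
    messages.append(text)
    if verbose:
        print(text)


# ---------------------------------------------------------------------------
# simulate


def stage_simulate(out_dir, spec: SyntheticSpec, verbose: bool = False) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kg, truth = gen_kg(spec)
    drugs = gen_smiles(spec.n_drugs, rng_seed=spec.seed + 2)
    ddi = gen_ddi(truth, spec)
    store = gen_embeddings(kg, spec.embedding_dim, mode="translational",
                           rng_seed=spec.seed + 3,
                           n_families=max(spec.n_classes - 1, 1))
    io.write_drug_table(drugs, out / "drugs.csv")
    io.write_ddi_table(ddi, out / "ddi.csv")
    io.write_triples(io.TripleFile(kg.triples()), out / "kg.tsv")
    io.write_embeddings(store, out / "embeddings.txt")
    with open(out / "truth.json", "w") as fh:
        json.dump({"pairs": [list(p) for p in truth.pairs],
                   "pathways": truth.pathways}, fh, indent=1, sort_keys=True)
    summary = {"n_drugs": len(drugs), "n_pairs": len(ddi),
               "kg_nodes": kg.n_nodes, "kg_edges": kg.n_edges,
               "n_planted": len(truth.pairs)}
    if verbose:
        print(f"simulate: {summary}")
    return summary


# ---------------------------------------------------------------------------
# preprocess


def stage_preprocess(data_dir, out_dir, cfg: RunConfig,
                     verbose: bool = False) -> dict:
    data, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sub_dir = out / "subgraphs"
    sub_dir.mkdir(exist_ok=True)
    log: list[str] = []

    drugs = io.read_drug_table(data / "drugs.csv")
    ddi = io.read_ddi_table(data / "ddi.csv")
    triples = io.read_triples(data / "kg.tsv")
    kg = kgmod.HeteroKG.from_triples(triples.triples)
    counts = {"initial": kgmod.stage_counts(kg)}
    _log(log, f"initial graph: nodes={kg.n_nodes} edges={kg.n_edges}", verbose)

    kg = kgmod.filter_families(kg, cfg.variant)
    counts[f"after_filtering_{cfg.variant}"] = kgmod.stage_counts(kg)
    _log(log, f"after {cfg.variant} filtering: nodes={kg.n_nodes} "
              f"edges={kg.n_edges}", verbose)

    kgmod.attach_self_loops(kg, drugs.drug_ids)
    use_sp = cfg.ablation not in _VARIANTS_WITHOUT_SP

    subgraphs: dict[str, kgmod.DrugSubgraph] = {}
    walk_sizes = []
    final_sizes = []
    for i, drug_id in enumerate(drugs.drug_ids):
        _, neighborhood = kgmod.random_walk_neighborhood(
            kg, drug_id, steps=cfg.walk_steps,
            restart_prob=cfg.walk_restart_prob,
            iterations=cfg.walk_iterations, spread=cfg.walk_spread,
            rng_seed=cfg.seed * 100_003 + i,
        )
        walk_sizes.append(kgmod.stage_counts(neighborhood))
        if use_sp:
            sub = kgmod.pathway_anchored_extract(drug_id, neighborhood,
                                                 hop_limit=cfg.hop_limit)
        else:
            sub = kgmod.DrugSubgraph(
                drug=drug_id,
                entities=set(neighborhood.graph.nodes),
                relations={r for _, r, _ in neighborhood.triples()},
                anchor_pathways=neighborhood.nodes_of_family("Pathway"),
                edges=neighborhood.triples(),
                families={n: neighborhood.family_of(n)
                          for n in neighborhood.graph.nodes},
            )
        final_sizes.append((len(sub.entities), len(sub.edges)))
        subgraphs[drug_id] = sub
        (sub_dir / _fname(drug_id)).write_text(sub.to_json())

    counts["random_walk_mean"] = tuple(
        float(np.mean([s[i] for s in walk_sizes])) for i in range(2))
    counts["final_mean"] = tuple(
        float(np.mean([s[i] for s in final_sizes])) for i in range(2))
    _log(log, f"random walk mean: nodes={counts['random_walk_mean'][0]:.2f} "
              f"edges={counts['random_walk_mean'][1]:.2f}", verbose)

    drugs_f, ddi_f, report = kgmod.consistency_filter(drugs, ddi, subgraphs)
    for drug_id, reason in report:
        _log(log, f"removed {drug_id}: {reason}", verbose)
        (sub_dir / _fname(drug_id)).unlink(missing_ok=True)
    _log(log, f"drugs {len(drugs)} -> {len(drugs_f)}; "
              f"interactions {len(ddi)} -> {len(ddi_f)}", verbose)

    io.write_drug_table(drugs_f, out / "drugs.csv")
    io.write_ddi_table(ddi_f, out / "ddi.csv")
    cfg.save(out / "config.yaml")
    with open(out / "preprocess_log.json", "w") as fh:
        json.dump({"counts": {k: list(v) for k, v in counts.items()},
                   "removed": [list(r) for r in report],
                   "log": log}, fh, indent=1, sort_keys=True)
    return {"n_drugs": len(drugs_f), "n_pairs": len(ddi_f),
            "removed": report, "counts": counts}


# ---------------------------------------------------------------------------
# embed


def save_matrices(matrices: dict[str, np.ndarray], path) -> None:
    """Deterministic plain-text serialization of the per-drug matrices."""
    with open(path, "w") as fh:
        for drug_id in sorted(matrices):
            M = matrices[drug_id]
            fh.write(f"# {drug_id} {M.shape[0]} {M.shape[1]}\n")
            for row in M:
                fh.write(" ".join(f"{x:.12g}" for x in row) + "\n")


def load_matrices(path) -> dict[str, np.ndarray]:
    matrices: dict[str, np.ndarray] = {}
    current: list[list[float]] | None = None
    name = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                if name is not None:
                    matrices[name] = np.array(current)
                name = line.split()[1]
                current = []
            elif line.strip():
                current.append([float(x) for x in line.split()])
    if name is not None:
        matrices[name] = np.array(current)
    return matrices


def stage_embed(data_dir, work_dir, verbose: bool = False) -> dict:
    data, work = Path(data_dir), Path(work_dir)
    drugs = io.read_drug_table(work / "drugs.csv")
    store = io.read_embeddings(data / "embeddings.txt")
    matrices = {}
    for drug_id in drugs.drug_ids:
        sub = kgmod.DrugSubgraph.from_json(
            (work / "subgraphs" / _fname(drug_id)).read_text()
        )
        matrices[drug_id] = build_matrix(sub, store).M
    save_matrices(matrices, work / "subgraph_matrices.txt")
    sizes = {d: m.shape[0] for d, m in matrices.items()}
    if verbose:
        print(f"embed: {len(matrices)} matrices, "
              f"mean S={np.mean(list(sizes.values())):.1f}")
    return {"n_matrices": len(matrices), "S": sizes,
            "dim": store.dim}


# ---------------------------------------------------------------------------
# train


def build_drug_batch(drugs: io.DrugTable, cfg: RunConfig,
                     vocab: tokenizer.Vocabulary,
                     matrices: dict[str, np.ndarray] | None) -> DrugBatch:
    ids, masks, adjs, atom_masks, mats = [], [], [], [], []
    for drug_id, smiles in drugs.records:
        seq = tokenizer.encode(smiles, vocab, L=cfg.L,
                               case_sensitive=cfg.case_sensitive)
        graph = parse_to_adjacency(seq.raw_tokens, cfg.L,
                                   add_self_loops=cfg.add_self_loops)
        ids.append(seq.ids)
        masks.append(seq.mask)
        adjs.append(graph.adjacency)
        atom_masks.append(graph.atom_mask)
        if matrices is not None:
            mats.append(matrices[drug_id])
    return DrugBatch(
        drug_ids=list(drugs.drug_ids),
        token_ids=np.stack(ids), token_mask=np.stack(masks),
        adjacency=np.stack(adjs), atom_mask=np.stack(atom_masks),
        subgraph_matrices=mats if matrices is not None else None,
    )


def _pair_arrays(ddi: io.DDITable, drug_index: dict[str, int],
                 task_mode: str) -> tuple[np.ndarray, np.ndarray]:
    pairs = np.array([[drug_index[a], drug_index[b]]
                      for a, b, _ in ddi.records], dtype=np.int64)
    labels = ddi.labels
    if task_mode == "binary":
        labels = (labels > 0).astype(np.int64)
    return pairs, labels


def _holdout_split(train_idx: np.ndarray, labels: np.ndarray,
                   rng: np.random.Generator,
                   frac: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Class-aware train/validation split inside one fold's training pairs."""
    val = []
    for c in np.unique(labels[train_idx]):
        members = train_idx[labels[train_idx] == c]
        n_val = max(1, int(round(frac * len(members)))) if len(members) > 1 else 0
        chosen = rng.choice(members, size=n_val, replace=False)
        val.extend(chosen.tolist())
    val = np.array(sorted(val), dtype=int)
    train = np.array(sorted(set(train_idx.tolist()) - set(val.tolist())),
                     dtype=int)
    if len(val) == 0:   # degenerate fallback: validate on the training set
        val = train
    return train, val


def stage_train(work_dir, cfg: RunConfig, verbose: bool = False) -> dict:
    work = Path(work_dir)
    drugs = io.read_drug_table(work / "drugs.csv")
    ddi = io.read_ddi_table(work / "ddi.csv")
    vocab = tokenizer.build_vocab([s for _, s in drugs.records],
                                  case_sensitive=cfg.case_sensitive)
    vocab.save(work / "vocab.json")
    needs_kg = "kg" in VARIANT_BLOCKS[cfg.ablation]
    matrices = load_matrices(work / "subgraph_matrices.txt") if needs_kg else None
    batch = build_drug_batch(drugs, cfg, vocab, matrices)
    drug_index = {d: i for i, d in enumerate(batch.drug_ids)}
    pairs, labels = _pair_arrays(ddi, drug_index, cfg.task_mode)
    n_classes = 2 if cfg.task_mode == "binary" else int(labels.max()) + 1

    plan = make_folds(ddi, k=cfg.n_folds, mode=cfg.split_mode,
                      rng_seed=cfg.seed)
    overlap = plan.overlap_certificate(ddi)
    matrices_hash = (
        hashlib.sha256((work / "subgraph_matrices.txt").read_bytes())
        .hexdigest() if needs_kg else None
    )

    fold_reports = []
    for fold_i, (train_idx, test_idx) in enumerate(plan.folds):
        fold_dir = work / f"fold_{fold_i}"
        fold_dir.mkdir(exist_ok=True)
        if needs_kg:
            # frozen-feature contract: the KG features seen by every fold
            # are the same artifact, re-serialized per fold for audit
            save_matrices(matrices, fold_dir / "subgraph_matrices.txt")
        if len(test_idx) == 0 or len(train_idx) == 0:
            fold_reports.append({"fold": fold_i, "skipped": "empty-fold"})
            continue
        rng = np.random.default_rng(cfg.seed * 1_000_003 + fold_i)
        model = DDIModel(cfg, vocab_size=len(vocab), n_classes=n_classes,
                         rng=np.random.default_rng(cfg.seed + 17))
        tr, val = _holdout_split(train_idx, labels, rng)
        result = train_fold(model, batch, pairs[tr], labels[tr],
                            pairs[val], labels[val], cfg, rng)
        result.write_history_csv(fold_dir / "history.csv")
        np.savez(fold_dir / "checkpoint.npz",
                 *[np.asarray(s) for s in result.checkpoint])
        report = evaluate(model, batch, pairs[test_idx], labels[test_idx],
                          n_classes)
        report.update({
            "fold": fold_i, "best_epoch": result.best_epoch,
            "stopped_early": result.stopped_early,
            "n_train": int(len(tr)), "n_val": int(len(val)),
            "n_test": int(len(test_idx)),
            "train_drug_overlap_with_test": overlap[fold_i],
        })
        fold_reports.append(report)
        if verbose:
            print(f"fold {fold_i}: acc={report['accuracy']:.4f} "
                  f"macroF1={report['macro']['f1']:.4f} "
                  f"best_epoch={result.best_epoch}")

    scored = [r for r in fold_reports if "accuracy" in r]
    summary = {
        "config": cfg.to_dict(),
        "n_classes": n_classes,
        "merged_classes": plan.merged_classes,
        "drug_overlap_certificate": overlap,
        "subgraph_matrices_sha256": matrices_hash,
        "folds": fold_reports,
        "mean_accuracy": float(np.mean([r["accuracy"] for r in scored]))
        if scored else None,
        "mean_macro_f1": float(np.mean([r["macro"]["f1"] for r in scored]))
        if scored else None,
    }
    with open(work / "metrics.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# evaluate (re-score a saved fold checkpoint)


def stage_evaluate(work_dir, cfg: RunConfig, fold: int = 0,
                   verbose: bool = False) -> dict:
    work = Path(work_dir)
    ckpt_path = work / f"fold_{fold}" / "checkpoint.npz"
    if not ckpt_path.exists():
        raise FileNotFoundError(f"missing checkpoint {ckpt_path}; train first")
    drugs = io.read_drug_table(work / "drugs.csv")
    ddi = io.read_ddi_table(work / "ddi.csv")
    vocab = tokenizer.Vocabulary.load(work / "vocab.json")
    needs_kg = "kg" in VARIANT_BLOCKS[cfg.ablation]
    matrices = load_matrices(work / "subgraph_matrices.txt") if needs_kg else None
    batch = build_drug_batch(drugs, cfg, vocab, matrices)
    drug_index = {d: i for i, d in enumerate(batch.drug_ids)}
    pairs, labels = _pair_arrays(ddi, drug_index, cfg.task_mode)
    n_classes = 2 if cfg.task_mode == "binary" else int(labels.max()) + 1
    plan = make_folds(ddi, k=cfg.n_folds, mode=cfg.split_mode,
                      rng_seed=cfg.seed)
    _, test_idx = plan.folds[fold]
    model = DDIModel(cfg, vocab_size=len(vocab), n_classes=n_classes,
                     rng=np.random.default_rng(cfg.seed + 17))
    with np.load(ckpt_path) as data:
        model.set_state([data[k] for k in sorted(data.files,
                                                 key=lambda s: int(s.split("_")[1]))])
    report = evaluate(model, batch, pairs[test_idx], labels[test_idx],
                      n_classes)
    if verbose:
        print(f"evaluate fold {fold}: acc={report['accuracy']:.4f}")
    return report


# ---------------------------------------------------------------------------
# explain


def stage_explain(work_dir, anchor: str | None = None,
                  label: int | None = None, coverage_min: float = 0.3,
                  alpha: float = 0.05, delta_min: float = 0.147,
                  plots: bool = False, verbose: bool = False) -> dict:
    work = Path(work_dir)
    sub_dir = work / "subgraphs"
    if not sub_dir.exists():
        raise FileNotFoundError(
            f"missing preprocess artifact {sub_dir}; run preprocess first"
        )
    ddi = io.read_ddi_table(work / "ddi.csv")
    subgraphs = {}
    for path in sorted(sub_dir.glob("*.json")):
        sub = kgmod.DrugSubgraph.from_json(path.read_text())
        subgraphs[sub.drug] = sub

    candidates = []
    if anchor is None or label is None:
        for a, b, lab in ddi.records:
            if lab > 0:
                candidates.append((a, lab))
                candidates.append((b, lab))
    tried = [(anchor, label)] if anchor is not None else candidates
    groups = None
    for cand_anchor, cand_label in tried:
        try:
            groups = partner_group_distributions(cand_anchor, cand_label,
                                                 ddi, subgraphs)
            anchor, label = cand_anchor, cand_label
            break
        except ValueError:
            continue
    if groups is None:
        raise ValueError("no anchor with both partner groups found")

    interacting, noninteracting, samples = groups
    records = screen_pathways(anchor, samples, coverage_min=coverage_min,
                              alpha=alpha, delta_min=delta_min)

    rows = [r.to_row() for r in records]
    with open(work / "pathway_ranking.tsv", "w") as fh:
        header = list(rows[0])
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[h]) for h in header) + "\n")

    merged = merge_subgraphs(subgraphs[anchor],
                             subgraphs[interacting[0]])
    with open(work / "merged_subgraph.json", "w") as fh:
        json.dump(merged.to_json_dict(), fh, indent=1, sort_keys=True)

    summaries = {}
    top = records[0]
    for c in CENTRALITY_ORDER:
        xi = samples[top.pathway].samples("interacting", c)
        yi = samples[top.pathway].samples("noninteracting", c)
        if len(xi) >= 2 and len(yi) >= 2:
            s = distribution_summary(xi, yi)
            summaries[c] = {"percentile_95": s.percentile_95,
                            "mean_difference": s.mean_difference,
                            "degenerate": s.degenerate}
            if plots:
                from .interpret import plot_distribution_summary
                plot_distribution_summary(
                    s, work / f"kde_{c}.png",
                    title=f"{top.pathway} ({c})")
    result = {
        "anchor": anchor, "label": int(label),
        "n_interacting": len(interacting),
        "n_noninteracting": len(noninteracting),
        "top_pathway": top.pathway,
        "top_passed": top.passed,
        "ranking": rows,
        "distribution_summaries": summaries,
    }
    with open(work / "explain.json", "w") as fh:
        json.dump(result, fh, indent=1, sort_keys=True)
    if verbose:
        print(f"explain: anchor={anchor} label={label} "
              f"top={top.pathway} passed={top.passed}")
    return result
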
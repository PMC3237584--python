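"""End-to-end orchestration: curate -> descriptors -> diversity split ->
cross-validated training -> benchmark -> score -> chemical-space and
fragment reports, driven by a single YAML config and recorded in a run
manifest sufficient to reproduce every output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemspace, descriptors, diversity, evaluation, fragments, models, synthetic
from .curation import (
    METABOLITE,
    NON_METABOLITE,
    CurationConfig,
    CurationReport,
    apply_filters,
    deduplicate_against,
    load_molecules,
    remove_annotated_drugs,
    wash_all,
    write_report,
    write_smiles,
)

logger = logging.getLogger(__name__)

VERSION = "0.1.0"

REQUIRED_KEYS = ("seed", "inputs", "split")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "runs/run",
    "inputs": {"metabolites": "fixture", "background": "fixture", "format": "smiles"},
    "curation": {
        "max_mol_weight": 1000.0,
        "min_atom_count": 3,
        "drug_annotation_fields": ["Taxonomy Family", "Taxonomy Sub Class"],
        "drug_patterns": ["drug"],
    },
    "descriptors": list(descriptors.DESCRIPTOR_KINDS),
    "diversity": {"threshold": 0.6},
    "split": {"n_per_class": None},  # None -> number of diversity centers
    "model": {"classifiers": ["rf", "svm", "nb"], "cv_folds": 5, "cutoff": 0.5, "grids": "small"},
    "chemspace": {"enabled": True, "variance_retained": 0.95, "kmax": 10},
    "fragments": {"enabled": True, "min_heavy": 4, "top_k": 20},
}


class SchemaError(ValueError):
    pass


def load_config(path_or_dict) -> dict:
    """Merge a YAML config (or dict) over the documented defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    for key in REQUIRED_KEYS:
        if key not in user:
            raise SchemaError(f"config missing required key: {key!r}")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


@dataclass
class RunManifest:
    version: str
    config: dict
    seeds: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_set(cfg: dict, which: str):
    src = cfg["inputs"][which]
    if src == "fixture":
        met, syn = synthetic.toy_molecule_fixture()
        return (met if which == "metabolites" else syn), "fixture"
    fmt = cfg["inputs"].get("format", "smiles")
    records = load_molecules(src, format=fmt)
    label = METABOLITE if which == "metabolites" else NON_METABOLITE
    for r in records:
        r.label = label
    return records, _sha256(Path(src))


def curate_sets(cfg: dict, manifest: RunManifest):
    """Wash + filter both input sets; drug-annotation removal on metabolites;
    deduplicate the background set against the metabolites."""
    ccfg = CurationConfig(**cfg["curation"])
    reports: dict[str, CurationReport] = {}
    sets = {}
    for which in ("metabolites", "background"):
        raw, checksum = _load_set(cfg, which)
        manifest.input_checksums[which] = checksum
        washed = wash_all(raw)
        kept, rep_f = apply_filters(washed, ccfg)
        reports[f"{which}/filters"] = rep_f
        if which == "metabolites":
            kept, rep_d = remove_annotated_drugs(kept, ccfg)
            reports["metabolites/drug_annotation"] = rep_d
        sets[which] = kept
        manifest.stage_counts[f"{which}_input"] = len(raw)
        manifest.stage_counts[f"{which}_curated"] = len(kept)
    sets["background"], rep_dedup = deduplicate_against(sets["background"], sets["metabolites"])
    reports["background/dedup_vs_metabolites"] = rep_dedup
    manifest.stage_counts["background_after_dedup"] = len(sets["background"])
    return sets["metabolites"], sets["background"], reports


def run_pipeline(config, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full workflow; idempotent for identical config + inputs."""
    cfg = load_config(config)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(version=VERSION, config=cfg)
    manifest.seeds = {"root": seed, "split": seed + 1, "model": seed + 2}

    # 1. curation
    met, bg, reports = curate_sets(cfg, manifest)
    write_smiles(met, out / "metabolites_curated.smi")
    write_smiles(bg, out / "background_curated.smi")
    write_report(reports, out / "curation_report.csv")

    # 2. descriptors
    kinds = cfg["descriptors"]
    all_records = {r.id: r for r in met + bg}
    matrices = {k: descriptors.descriptor_matrix(met + bg, k) for k in kinds}
    for k, m in matrices.items():
        m.to_csv(out / f"descriptors_{k}.csv")

    # 3. diversity selection on metabolite ECFP_4 + balanced split
    fps = [descriptors.fingerprint(r, "ecfp4") for r in met]
    partition = diversity.max_dissimilarity_partition(
        fps,
        threshold=float(cfg["diversity"]["threshold"]),
        sort_keys=[r.structure for r in met],
    )
    manifest.stage_counts["diversity_centers"] = partition.n_clusters
    centers = partition.centers
    rest = [r.id for r in met if r.id not in set(centers)]
    n_per_class = cfg["split"].get("n_per_class") or len(centers)
    n_per_class = min(int(n_per_class), len(bg))
    split = diversity.assemble_training_sets(
        centers, [r.id for r in bg], n_per_class, seed=manifest.seeds["split"], metab_rest=rest
    )
    rows = []
    for mid in split.train_ids + split.test_ids:
        role = "train" if mid in set(split.train_ids) else "test"
        rows.append(
            {
                "id": mid,
                "class": all_records[mid].label,
                "role": role,
                "center": partition.assignment.get(mid, ""),
            }
        )
    pd.DataFrame(rows).to_csv(out / "split_manifest.csv", index=False)
    manifest.stage_counts["train"] = len(split.train_ids)
    manifest.stage_counts["test"] = len(split.test_ids)

    # 4. benchmark grid (one tuned model per descriptor x classifier cell)
    def xy(ids, kind):
        X = matrices[kind].loc[ids].to_numpy(dtype=float)
        y = np.array([1 if all_records[i].label == METABOLITE else 0 for i in ids])
        return X, y

    train_ids, test_ids = split.train_ids, split.test_ids
    train_data = {k: xy(train_ids, k) for k in kinds}
    test_data = {k: xy(test_ids, k) for k in kinds}
    mcfg = cfg["model"]
    table, trained = evaluation.benchmark_grid(
        train_data,
        test_data,
        kinds,
        mcfg["classifiers"],
        seed=manifest.seeds["model"],
        cv_k=int(mcfg["cv_folds"]),
        small_grids=mcfg.get("grids", "small") == "small",
        cutoff=float(mcfg["cutoff"]),
    )
    table.to_dataframe().to_csv(out / "benchmark.csv", index=False)
    manifest.stage_counts["benchmark_cells"] = len(table.cells)

    # best cell by test AUC -> score histograms per class
    best_d, best_c = max(table.cells, key=lambda k: table.cells[k]["auc"])
    manifest.outputs["best_cell"] = f"{best_d}/{best_c}"
    best_model = trained[(best_d, best_c)]
    hist_rows = []
    for name, ids in (("metabolites", split.test_metab), ("background", split.test_background)):
        if not ids:
            continue
        X, _ = xy(ids, best_d)
        scores = models.metabolite_likeness(best_model, X)
        hist = evaluation.score_histogram(scores, name)
        for lo, hi, c in zip(hist.edges[:-1], hist.edges[1:], hist.counts):
            hist_rows.append({"set": name, "bin_low": lo, "bin_high": hi, "count": int(c)})
    pd.DataFrame(hist_rows).to_csv(out / "score_histograms.csv", index=False)

    # 5. chemical-space reports on the training set
    if cfg["chemspace"].get("enabled", True):
        space_kind = "pp_desc" if "pp_desc" in matrices else kinds[0]
        Xtr, ytr = train_data[space_kind]
        pres = chemspace.pca(Xtr, standardize=True, columns=list(matrices[space_kind].columns))
        ncomp = pres.n_components_for(float(cfg["chemspace"].get("variance_retained", 0.95)))
        dend = chemspace.ward_cluster(pres.scores[:, :ncomp])
        labels = chemspace.cut_by_inertia(dend, kmax=int(cfg["chemspace"].get("kmax", 10)))
        contingency = chemspace.ClusterContingency.from_labels(labels, ytr)
        purity = chemspace.cluster_purity(contingency)
        pd.DataFrame(
            {
                "cluster": contingency.counts.index,
                **{c: contingency.counts[c].values for c in contingency.counts.columns},
                "purity_percent": purity,
            }
        ).to_csv(out / "clusters.csv", index=False)
        pd.DataFrame(
            pres.scores[:, :ncomp], index=train_ids, columns=[f"PC{i+1}" for i in range(ncomp)]
        ).to_csv(out / "pca_scores.csv")
        manifest.stage_counts["clusters"] = int(labels.max())

        # conditional inference tree on unhashed ECFP_4 features
        feats: dict[int, set[str]] = {}
        for mid in train_ids:
            sp = descriptors.circular_fingerprint(all_records[mid], 4, "atom_type")
            for f in sp.feature_ids:
                feats.setdefault(f, set()).add(mid)
        common = sorted(f for f, mids in feats.items() if len(mids) >= 5)
        Xcit = np.array(
            [[1 if mid in feats[f] else 0 for f in common] for mid in train_ids], dtype=int
        )
        tree = chemspace.conditional_inference_tree(
            Xcit, ytr, alpha=0.05, min_node=20, feature_names=[str(f) for f in common]
        )
        (out / "cit.txt").write_text(tree.render() + "\n")
        (out / "cit.dot").write_text(tree.to_dot() + "\n")

    # 6. fragment tables
    if cfg["fragments"].get("enabled", True):
        fcfg = cfg["fragments"]
        table_f = fragments.fragment_frequency(
            met, bg, min_heavy=int(fcfg["min_heavy"]), top_k=int(fcfg["top_k"])
        )
        pd.DataFrame(
            [
                {
                    "kind": f.kind,
                    "smiles": f.structure,
                    "heavy_atoms": f.heavy_atoms,
                    "freq_metabolites": f.freq_a,
                    "freq_background": f.freq_b,
                }
                for f in table_f
            ]
        ).to_csv(out / "fragments_metabolites.csv", index=False)

    manifest.outputs.update(
        {
            "benchmark": str(out / "benchmark.csv"),
            "split_manifest": str(out / "split_manifest.csv"),
            "curation_report": str(out / "curation_report.csv"),
        }
    )
    manifest.write(out / "manifest.json")
    return manifest
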
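"""End-to-end orchestration of the organotropism architecture.

Stages: clinical labeling -> tumor-type classification -> per-(cancer, site)
binary modeling (split / balance / select / train / evaluate) -> feature
recapture -> GO enrichment and the weighted overlap null. Stages communicate
through files in the output directory; a manifest records the configuration
hash, seeds, and the SHA-256 of every artifact, so a rerun with the same
config is bit-identical and cached stages can be skipped safely.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clinical as clin
from ._util import sha256_file, write_id_list, read_id_list
from .balancing import SmoteConfig
from .enrichment import GmtAnnotation, NullSimConfig, go_overrepresentation, weighted_overlap_null
from .preprocess import log_cpm
from .recapture import recapture_matrix
from .selection import SelectionConfig
from .site import SiteProgressionModel, aggregate_by_cancer, report_from_counts
from .simulate import read_dag_edges
from .tumor_type import TumorTypeModel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression: str
    clinical: str
    gmt: str | None = None
    dag: str | None = None
    out_dir: str = "out"
    seed: int = 0
    model_kind: str = "rf"
    holdout_fraction: float = 0.3
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    pair_filter: clin.PairFilterConfig = field(default_factory=clin.PairFilterConfig)
    null_sim: NullSimConfig = field(default_factory=NullSimConfig)
    run_null: bool = False
    cache: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("smote", SmoteConfig), ("selection", SelectionConfig),
                         ("pair_filter", clin.PairFilterConfig),
                         ("null_sim", NullSimConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path, cache: bool):
        self.path = path
        self.cache = cache
        self.data: dict = {"stages": {}}
        self.prev: dict = {}
        if cache and path.exists():
            self.prev = json.loads(path.read_text()).get("stages", {})

    def cached(self, stage: str, inputs_hash: str, outputs: list[Path]) -> bool:
        ent = self.prev.get(stage)
        ok = (self.cache and ent is not None and ent["inputs_hash"] == inputs_hash
              and all(p.exists() for p in outputs))
        if ok:
            self.data["stages"][stage] = ent
        return ok

    def record(self, stage: str, inputs_hash: str, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "inputs_hash": inputs_hash,
            "outputs": {p.name: sha256_file(p) for p in sorted(outputs)},
        }

    def save(self, header: dict) -> None:
        self.data.update(header)
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the manifest dict.

    Any stage failure raises with the stage name (and offending pair) in the
    message. A configuration yielding zero retained pairs completes with
    empty pair-level outputs and a warning.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json", cfg.cache)
    cfg_hash = _hash_obj(cfg.to_jsonable())

    expr_counts = pd.read_csv(cfg.expression, sep="\t", index_col=0)
    clinical = clin.read_clinical(cfg.clinical)
    X = log_cpm(expr_counts)

    # ---- stage: labels -------------------------------------------------
    stage = "labels"
    try:
        table = clin.harmonize_sites(clinical)
        if cfg.pair_filter.merge_coadread:
            table = clin.merge_coadread(table)
        pairs = clin.enumerate_pairs(table)
        label_sets = [clin.build_progression_labels(table, c, s) for c, s in pairs]
        catalog = clin.filter_pairs(label_sets, cfg.pair_filter)
        catalog.to_csv(out / "pair_catalog.tsv", sep="\t", index=False)
        by_pair = {(ls.cancer_code, ls.site): ls for ls in label_sets}
        manifest.record(stage, _hash_obj([cfg_hash, stage]), [out / "pair_catalog.tsv"])
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e
    if catalog.empty:
        warnings.warn("no (cancer, site) pair passed the population filters; "
                      "pair-level stages will be empty")

    # ---- stage: tumor type ---------------------------------------------
    stage = "tumor_type"
    try:
        tt = TumorTypeModel(X, table["cancer_code"], merge_coadread=False,
                            holdout_fraction=cfg.holdout_fraction, seed=cfg.seed).fit()
        tt.report.confusion.to_csv(out / "tumor_type_confusion.tsv", sep="\t")
        (out / "tumor_type_report.json").write_text(json.dumps({
            "macro_precision": tt.report.macro_precision,
            "macro_recall": tt.report.macro_recall,
            "macro_f1": tt.report.macro_f1,
        }, indent=1, sort_keys=True))
        manifest.record(stage, _hash_obj([cfg_hash, stage]),
                        [out / "tumor_type_confusion.tsv", out / "tumor_type_report.json"])
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e

    # ---- stage: per-pair binary models ---------------------------------
    reports = []
    feature_dir = out / "features"
    feature_dir.mkdir(exist_ok=True)
    for _, row in catalog.iterrows():
        pair = (row["cancer_code"], row["site"])
        stage = f"site:{pair[0]}|{pair[1]}"
        slug = f"{pair[0]}_{pair[1]}".replace(" ", "-")
        outs = [feature_dir / f"{slug}.top.txt", out / f"site_{slug}.json"]
        ihash = _hash_obj([cfg_hash, stage])
        if manifest.cached(stage, ihash, outs):
            rep = json.loads(outs[1].read_text())
            reports.append(report_from_counts(rep["tp"], rep["fp"], rep["fn"],
                                              rep["tn"], pair))
            continue
        try:
            res = SiteProgressionModel(
                X, by_pair[pair], model_kind=cfg.model_kind,
                smote_cfg=dataclasses.replace(cfg.smote, seed=cfg.seed),
                selection_cfg=dataclasses.replace(cfg.selection, seed=cfg.seed),
                holdout_fraction=cfg.holdout_fraction, seed=cfg.seed).fit()
            top = res.selection.top if res.selection is not None else res.features
            write_id_list(top, outs[0])
            outs[1].write_text(json.dumps(res.report.to_dict(), indent=1, sort_keys=True))
            reports.append(res.report)
            manifest.record(stage, ihash, outs)
        except Exception as e:
            raise RuntimeError(f"stage 'site_classifier' failed for pair {pair}: {e}") from e

    if reports:
        aggregate_by_cancer(reports).to_csv(out / "cancer_aggregate.tsv",
                                            sep="\t", index=False)

    # ---- stage: recapture ----------------------------------------------
    stage = "recapture"
    try:
        lists = {p.stem.replace(".top", ""): read_id_list(p)
                 for p in sorted(feature_dir.glob("*.top.txt"))}
        rec = recapture_matrix(lists, list(X.columns)) if len(lists) >= 2 else pd.DataFrame()
        rec.to_csv(out / "recapture.tsv", sep="\t", index=False)
        manifest.record(stage, _hash_obj([cfg_hash, stage]), [out / "recapture.tsv"])
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e

    # ---- stage: enrichment + null --------------------------------------
    if cfg.gmt:
        stage = "enrichment"
        try:
            ann = GmtAnnotation.from_gmt(cfg.gmt)
            enr_outs = []
            for name, ids in sorted(lists.items()):
                enr = go_overrepresentation(ids, ann)
                p = out / f"enrichment_{name}.tsv"
                enr.to_csv(p, sep="\t")
                enr_outs.append(p)
            if cfg.run_null:
                null = weighted_overlap_null(
                    ann, dataclasses.replace(cfg.null_sim, seed=cfg.seed))
                null.to_tsv(out / "overlap_null.tsv")
                enr_outs.append(out / "overlap_null.tsv")
            manifest.record(stage, _hash_obj([cfg_hash, stage]), enr_outs)
        except Exception as e:
            raise RuntimeError(f"stage '{stage}' failed: {e}") from e
        if cfg.dag:
            read_dag_edges(cfg.dag)  # validated here; clustering is on-demand

    manifest.save({"config_hash": cfg_hash, "seed": cfg.seed,
                   "n_pairs": int(len(catalog))})
    return manifest.data
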
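"""One-vs-all evaluation, the random-guess baseline, and the experiment matrix.

Each class in turn is treated as the positive class: TP counts instances of
the class predicted as the class, FP counts other instances predicted as the
class, FN counts instances of the class predicted otherwise.  Precision
P = TP/(TP+FP), recall R = TP/(TP+FN) and F1 = 2PR/(P+R), with the 0/0 case
defined as 0.  Macro averages are unweighted means over the five classes.

With balanced classes, uniform random guessing attains expected per-class
precision = recall = 1/k (0.20 for five classes); both the analytic value
and a Monte-Carlo simulation of it are provided as the floor any trained
system must clear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .synthesis import CLASSES


@dataclass
class EvalReport:
    """Per-class and macro P/R/F1 plus the raw confusion matrix."""

    classes: tuple[str, ...]
    per_class: dict[str, tuple[float, float, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray  # rows gold, columns predicted
    n: int

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for cls in self.classes:
            p, r, f = self.per_class[cls]
            row[f"{cls}_P"] = p
            row[f"{cls}_R"] = r
            row[f"{cls}_F1"] = f
        row["macro_P"] = self.macro_precision
        row["macro_R"] = self.macro_recall
        row["macro_F1"] = self.macro_f1
        return row


def one_vs_all_counts(
    gold: Sequence[str], pred: Sequence[str], target: str
) -> tuple[int, int, int]:
    """(TP, FP, FN) for ``target`` as the positive class."""
    if len(gold) != len(pred):
        raise ValueError("gold and predicted label sequences differ in length")
    tp = sum(1 for g, p in zip(gold, pred) if g == target and p == target)
    fp = sum(1 for g, p in zip(gold, pred) if g != target and p == target)
    fn = sum(1 for g, p in zip(gold, pred) if g == target and p != target)
    return tp, fp, fn


def evaluate(
    gold: Sequence[str], pred: Sequence[str], classes: Sequence[str] = CLASSES
) -> EvalReport:
    """One-vs-all P/R/F1 per class plus unweighted macro averages."""
    if len(gold) != len(pred):
        raise ValueError("gold and predicted label sequences differ in length")
    classes = tuple(classes)
    p, r, f, _ = precision_recall_fscore_support(
        gold, pred, labels=list(classes), zero_division=0
    )
    per_class = {
        cls: (float(p[i]), float(r[i]), float(f[i])) for i, cls in enumerate(classes)
    }
    conf = confusion_matrix(gold, pred, labels=list(classes))
    return EvalReport(
        classes=classes,
        per_class=per_class,
        macro_precision=float(np.mean(p)),
        macro_recall=float(np.mean(r)),
        macro_f1=float(np.mean(f)),
        confusion=conf,
        n=len(gold),
    )


def macro_f1(gold: Sequence[str], pred: Sequence[str],
             classes: Sequence[str] = CLASSES) -> float:
    return evaluate(gold, pred, classes).macro_f1


def random_baseline(
    n_classes: int = 5,
    per_class: int = 500,
    mode: str = "analytic",
    seed: int = 0,
    n_draws: int = 100_000,
) -> EvalReport:
    """Uniform random-guess floor on a balanced ``n_classes``-way setting.

    ``analytic`` returns the expectation (P = R = F1 = 1/k per class);
    ``monte_carlo`` simulates uniform predictions over ``n_draws`` balanced
    instances and converges to the same values.
    """
    if n_classes < 1 or per_class < 1:
        raise ValueError("class and instance counts must be positive")
    classes = tuple(CLASSES[:n_classes]) if n_classes <= len(CLASSES) else tuple(
        f"C{i}" for i in range(n_classes)
    )
    if mode == "analytic":
        value = 1.0 / n_classes
        per = {cls: (value, value, value) for cls in classes}
        conf = np.full((n_classes, n_classes), per_class / n_classes)
        return EvalReport(
            classes=classes,
            per_class=per,
            macro_precision=value,
            macro_recall=value,
            macro_f1=value,
            confusion=conf,
            n=n_classes * per_class,
        )
    if mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        gold = [classes[i % n_classes] for i in range(n_draws)]
        pred = [classes[int(i)] for i in rng.integers(n_classes, size=n_draws)]
        return evaluate(gold, pred, classes)
    raise ValueError(f"unknown baseline mode {mode!r}")


@dataclass
class MatrixRow:
    name: str
    report: EvalReport | None
    error: str | None = None
    seed: int | None = None


@dataclass
class MatrixReport:
    """Variant-by-variant results with the per-class column layout."""

    rows: list[MatrixRow] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            if row.report is None:
                records.append({"variant": row.name, "error": row.error})
            else:
                records.append({"variant": row.name, **row.report.as_row()})
        return pd.DataFrame(records)

    def write_tsv(self, path, header: str = "") -> None:
        df = self.to_dataframe()
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(f"# {header}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.4f")

    def render(self) -> str:
        return self.to_dataframe().to_string(index=False, float_format="%.3f")


@dataclass
class MatrixConfig:
    """Everything ``run_matrix`` needs besides the corpus splits."""

    encoder: object = None  # text encoder; defaults to HashedBowEncoder
    term_names: dict[str, str] | None = None
    goa_tables: dict[str, object] | None = None  # split name -> NodeEmbeddingTable
    dag_table: object = None
    dummy_goa_tables: dict[str, object] | None = None
    dummy_dag_table: object = None
    classifier_cfg: object = None
    seed: int = 0


def run_matrix(
    variant_names: Sequence[str],
    splits: tuple[Sequence, Sequence, Sequence],
    cfg: MatrixConfig,
) -> MatrixReport:
    """Train and evaluate each requested variant on the given splits.

    ``"baseline"`` rows are the analytic random-guess floor.  A variant whose
    prerequisite tables are missing is recorded as a per-row failure and the
    matrix continues.
    """
    from .joint_model import (
        VARIANTS,
        ClassifierConfig,
        FeatureTables,
        HashedBowEncoder,
        train_classifier,
    )

    train, dev, test = splits
    encoder = cfg.encoder or HashedBowEncoder()
    classifier_cfg = cfg.classifier_cfg or ClassifierConfig(seed=cfg.seed)
    report = MatrixReport()
    test_gold = [inst.label for inst in test]
    for name in variant_names:
        if name == "baseline":
            n_per = max(len(test) // len(CLASSES), 1)
            report.rows.append(
                MatrixRow(
                    name,
                    random_baseline(len(CLASSES), n_per, mode="analytic"),
                    seed=cfg.seed,
                )
            )
            continue
        if name not in VARIANTS:
            report.rows.append(MatrixRow(name, None, error=f"unknown variant {name!r}"))
            continue
        variant = VARIANTS[name]
        try:
            tables = _tables_for(variant, cfg)
            model = train_classifier(
                train,
                dev,
                variant,
                classifier_cfg,
                encoder=encoder,
                term_names=cfg.term_names,
                train_tables=tables["train"],
                dev_tables=tables["dev"],
            )
            pred = model.predict_batch(test, tables["test"])
            report.rows.append(
                MatrixRow(name, evaluate(test_gold, pred), seed=cfg.seed)
            )
        except (ValueError, KeyError) as exc:
            report.rows.append(MatrixRow(name, None, error=str(exc)))
    return report


def _tables_for(variant, cfg: MatrixConfig) -> dict[str, "FeatureTables"]:
    from .joint_model import FeatureTables

    out: dict[str, FeatureTables] = {}
    for split in ("train", "dev", "test"):
        goa = dag = None
        if "goa_table" in variant.uses:
            if cfg.goa_tables is None or split not in cfg.goa_tables:
                raise ValueError(
                    f"variant {variant.name} requires a GOA table for {split}"
                )
            goa = cfg.goa_tables[split]
        if "dag_table" in variant.uses:
            if cfg.dag_table is None:
                raise ValueError(f"variant {variant.name} requires a DAG table")
            dag = cfg.dag_table
        if "dummy_table" in variant.uses:
            if cfg.dummy_goa_tables is None or cfg.dummy_dag_table is None:
                raise ValueError(
                    f"variant {variant.name} requires dummy tables"
                )
            goa = cfg.dummy_goa_tables[split]
            dag = cfg.dummy_dag_table
        out[split] = FeatureTables(goa=goa, dag=dag)
    return out
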
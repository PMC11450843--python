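"""End-to-end mining flow: train, classify, precursor search, masses.

The production-scale study behind this workflow screened NCBI-scale
sequence sets; this implementation operates strictly on local files
(protein FASTAs and GenBank nucleotide records supplied by the user)
with identical semantics, which keeps every stage reproducible and
testable at desk scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from atropomine.classifier import (
    ClassifierConfig,
    ClassifierResults,
    P450ClassifierModel,
)
from atropomine.masses import candidate_series, match_observed
from atropomine.neighborhood import (
    DEFAULT_FLANK,
    DEFAULT_MOTIFS,
    MotifSet,
    extract_neighborhood,
    find_anchor,
    find_precursors,
    write_region_genbank,
)
from atropomine.seqprep import (
    CLASSIFICATION_LENGTH_FILTER,
    DEFAULT_ALPHABET,
    DereplicationParams,
    ProteinSeq,
    ReducedAlphabet,
    ReferenceScheme,
    dereplicate,
    read_fasta,
)

logger = logging.getLogger("atropomine")


@dataclass
class RunConfig:
    """Paths and parameters for a full mining run."""

    reference_path: Path
    positives_path: Path
    negatives_path: Path
    out_dir: Path
    query_path: Path | None = None
    genbank_paths: tuple[Path, ...] = ()
    cut_positions: tuple[int, int, int, int] = (92, 192, 275, 395)
    alphabet: ReducedAlphabet = field(default_factory=lambda: DEFAULT_ALPHABET)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    derep: DereplicationParams = field(default_factory=DereplicationParams)
    motifs: MotifSet = field(default_factory=lambda: DEFAULT_MOTIFS)
    rule_mode: str = "leader-motif"
    flank: int = DEFAULT_FLANK
    seed: int = 0

    def scheme(self) -> ReferenceScheme:
        ref = read_fasta(self.reference_path)[0]
        return ReferenceScheme(reference=ref, cut_positions=self.cut_positions)


@dataclass
class PipelineReport:
    """Per-stage counts of the mining funnel."""

    counts: dict[str, int] = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    version: str = ""

    def validate(self) -> None:
        for key, value in self.counts.items():
            if value < 0:
                raise ValueError(f"negative count for {key}")
        found = self.counts.get("precursors_found")
        scanned = self.counts.get("orfs_scanned")
        if found is not None and scanned is not None and found > scanned:
            raise ValueError("precursors found exceed ORFs scanned")

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "config": self.config_echo,
                "version": self.version,
            },
            indent=2,
        )


def _require(path: Path | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"no {what} configured")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} not found: {path}")
    return path


def run_train(config: RunConfig) -> ClassifierResults:
    """Dereplicate training sets, build the model, fit, write artifacts."""
    from atropomine import __version__

    positives = read_fasta(_require(config.positives_path, "positive set"))
    negatives = read_fasta(_require(config.negatives_path, "negative set"))
    scheme = config.scheme()
    logger.info(
        "train: %d positives, %d negatives before dereplication",
        len(positives), len(negatives),
    )
    positives = dereplicate(positives, config.derep)
    negatives = dereplicate(negatives, config.derep)
    logger.info(
        "train: %d positives, %d negatives after dereplication",
        len(positives), len(negatives),
    )
    model = P450ClassifierModel.from_sequences(
        positives, negatives, scheme, config.alphabet
    )
    cls_config = ClassifierConfig(
        n_trees=config.classifier.n_trees,
        max_depth=config.classifier.max_depth,
        min_samples_leaf=config.classifier.min_samples_leaf,
        split_fraction=config.classifier.split_fraction,
        score_threshold=config.classifier.score_threshold,
        seed=config.seed,
    )
    results = model.fit(cls_config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "feature_space.json").write_text(model.feature_space.to_json())
    eval_payload = dict(results.report.as_dict())
    eval_payload["seed"] = config.seed
    eval_payload["version"] = __version__
    (out / "eval.json").write_text(json.dumps(eval_payload, indent=2))
    (out / "summary.txt").write_text(results.summary() + "\n")
    logger.info("train: artifacts written to %s", out)
    return results


def classify_fasta(
    results: ClassifierResults,
    query_path: Path,
    scheme: ReferenceScheme,
    alphabet: ReducedAlphabet = DEFAULT_ALPHABET,
    length_filter: tuple[int, int] = CLASSIFICATION_LENGTH_FILTER,
) -> pd.DataFrame:
    """Classify a query FASTA; returns a (id, score, label) table.

    Sequences outside the classification length window are reported
    with label ``length_filtered`` and no score.
    """
    queries = read_fasta(query_path)
    rows = []
    lo, hi = length_filter
    in_range = [q for q in queries if lo <= len(q) <= hi]
    skipped = [q for q in queries if not lo <= len(q) <= hi]
    if in_range:
        labels, scores = results.classify_proteins(in_range, scheme, alphabet)
        for q, lab, sc in zip(in_range, labels, scores):
            rows.append(
                {
                    "id": q.id.split()[0],
                    "score": float(sc),
                    "label": "positive" if lab else "negative",
                }
            )
    for q in skipped:
        rows.append(
            {"id": q.id.split()[0], "score": float("nan"),
             "label": "length_filtered"}
        )
    return pd.DataFrame(rows, columns=["id", "score", "label"])


def _load_records(paths: Sequence[Path]):
    records = []
    for path in paths:
        records.extend(SeqIO.parse(str(path), "genbank"))
    return records


def run_mine(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, PipelineReport]:
    """Classify queries, then search neighborhoods of positives.

    Returns (classification table, precursor summary table, report) and
    writes results.tsv, precursors.tsv, region GenBank files and
    report.json to the output directory.
    """
    from atropomine import __version__

    results = run_train(config)
    scheme = config.scheme()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    query_path = _require(config.query_path, "query FASTA")
    try:
        table = classify_fasta(results, query_path, scheme, config.alphabet)
    except ValueError:  # empty query FASTA
        table = pd.DataFrame(columns=["id", "score", "label"])
    table.to_csv(out / "results.tsv", sep="\t", index=False)
    positives = table[table["label"] == "positive"]["id"].tolist()

    records = _load_records(
        [_require(p, "GenBank record") for p in config.genbank_paths]
    )
    precursor_rows = []
    n_neighborhoods = 0
    n_orfs = 0
    for pid in positives:
        hit = None
        for record in records:
            try:
                anchor = find_anchor(record, pid)
                hit = (record, anchor)
                break
            except ValueError:
                continue
        if hit is None:
            logger.warning(
                "mine: %s classified positive but absent from all GenBank "
                "records; skipped from the precursor stage", pid
            )
            continue
        record, anchor = hit
        nb = extract_neighborhood(record, anchor, config.flank)
        n_neighborhoods += 1
        from atropomine.neighborhood import scan_orfs

        n_orfs += len(scan_orfs(nb))
        found = find_precursors(
            nb, rule_mode=config.rule_mode, motifs=config.motifs
        )
        region_path = out / f"region_{pid.replace('.', '_')}.gbk"
        write_region_genbank(nb, found, region_path)
        for cand in found:
            precursor_rows.append(
                {
                    "record": record.id,
                    "anchor": pid,
                    "start": cand.orf.start + 1,
                    "end": cand.orf.end,
                    "strand": "+" if cand.orf.strand == 1 else "-",
                    "leader": cand.leader,
                    "core": cand.core,
                    "motif": cand.matched_motif or "",
                    "rule_mode": cand.rule_mode,
                }
            )
    precursors = pd.DataFrame(
        precursor_rows,
        columns=[
            "record", "anchor", "start", "end", "strand", "leader",
            "core", "motif", "rule_mode",
        ],
    )
    precursors.to_csv(out / "precursors.tsv", sep="\t", index=False)

    report = PipelineReport(
        counts={
            "queries": int(len(table)),
            "classified_positive": len(positives),
            "neighborhoods_scanned": n_neighborhoods,
            "orfs_scanned": n_orfs,
            "precursors_found": len(precursors),
        },
        config_echo={
            "rule_mode": config.rule_mode,
            "flank": config.flank,
            "seed": config.seed,
            "score_threshold": config.classifier.score_threshold,
        },
        version=__version__,
    )
    report.validate()
    (out / "report.json").write_text(report.to_json())
    return table, precursors, report


def run_masses(
    cores: Sequence[dict],
    observed: Sequence[float] = (),
    tolerance_ppm: float = 5.0,
) -> pd.DataFrame:
    """Candidate-ion table for core peptides.

    ``cores`` rows carry ``core`` plus optional ``max_crosslinks`` and
    ``allow_n_truncations``. With observed masses supplied, matching
    rows gain the observed m/z and signed ppm error.
    """
    rows = []
    for i, row in enumerate(cores):
        try:
            core = str(row["core"]).strip().upper()
            max_x = int(row.get("max_crosslinks", 3))
            trunc = int(row.get("allow_n_truncations", 1))
            series = candidate_series(core, max_x, trunc)
        except (KeyError, ValueError, TypeError) as exc:
            logger.error("masses: row %d malformed (%s); skipped", i + 1, exc)
            continue
        matches = match_observed(series, observed, tolerance_ppm)
        matched_ids = {id(c): (obs, err) for obs, c, err in matches}
        for cand in series:
            entry = {
                "core": core,
                "peptide": cand.peptide,
                "truncation": cand.truncation,
                "n_crosslinks": cand.n_crosslinks,
                "formula": cand.formula.hill(),
                "mz_calc": cand.mz,
            }
            if id(cand) in matched_ids:
                obs, err = matched_ids[id(cand)]
                entry["mz_obs"] = obs
                entry["ppm"] = round(err, 2)
            rows.append(entry)
    columns = [
        "core", "peptide", "truncation", "n_crosslinks", "formula",
        "mz_calc", "mz_obs", "ppm",
    ]
    return pd.DataFrame(rows, columns=columns)
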
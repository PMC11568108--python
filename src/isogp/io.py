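"""Readers/writers for count panels and design matrices, and run plumbing.

Text formats only: counts as TSV/CSV with cells as rows and antibodies as
columns, or as a MatrixMarket triplet with sidecar name files
(``<file>.cells`` and ``<file>.antibodies``, one name per line).  Designs are
TSV/CSV with a leading ``mu0`` intercept column; non-contiguous level codes
are re-indexed to ``1..L`` and the mapping is logged and retained.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from ._types import ADTCountMatrix, DesignMatrix
from .model import PriorConfig

log = logging.getLogger("isogp")

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "RunConfig",
    "run_fit_command",
]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx_triplet"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_counts(path, format: str | None = None, isotype_pattern: str = "IgG") -> ADTCountMatrix:
    """Load a cells-x-antibodies count panel.

    Antibodies whose name contains ``isotype_pattern`` are auto-flagged as
    isotype controls; flags can be overridden on the returned object.
    Negative or non-integer entries are a format error, never clipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"counts file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dupes = {h for h in header if header.count(h) > 1}
        if dupes:
            # pandas would silently rename these, hiding the problem
            raise ValueError(f"duplicate antibody name(s) in header: {sorted(dupes)}")
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = ADTCountMatrix.from_frame(df)
    elif fmt == "mtx_triplet":
        cells_file = path.with_suffix(path.suffix + ".cells")
        abs_file = path.with_suffix(path.suffix + ".antibodies")
        for f in (cells_file, abs_file):
            if not f.exists():
                raise FileNotFoundError(f"MTX triplet requires name file: {f}")
        m = spio.mmread(path)
        counts = np.asarray(m.todense() if sparse.issparse(m) else m)
        cells = cells_file.read_text().split()
        antibodies = abs_file.read_text().split()
        mat = ADTCountMatrix(counts=counts, antibody_names=antibodies, cell_ids=cells)
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    if isotype_pattern != "IgG":
        mat.isotype_flags = np.array(
            [isotype_pattern in n for n in mat.antibody_names], dtype=bool
        )
    return mat


def write_counts(matrix: ADTCountMatrix, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("tsv", "csv"):
        matrix.to_frame().to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx_triplet":
        spio.mmwrite(path, sparse.coo_matrix(matrix.counts))
        path.with_suffix(path.suffix + ".cells").write_text(
            "\n".join(matrix.cell_ids) + "\n"
        )
        path.with_suffix(path.suffix + ".antibodies").write_text(
            "\n".join(matrix.antibody_names) + "\n"
        )
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_design(path) -> DesignMatrix:
    """Load and validate a design matrix.

    The first column must be named ``mu0`` and contain only ones.  Integer
    covariate codes that are not contiguous ``1..L`` are re-indexed in sorted
    order; the mapping is logged and stored on ``DesignMatrix.level_maps``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"design file not found: {path}")
    df = pd.read_csv(path, sep="\t" if path.suffix.lower() != ".csv" else ",")
    if df.shape[1] < 1 or df.columns[0] != "mu0":
        raise ValueError(
            'the first design column must be named "mu0" and hold the constant intercept 1'
        )
    level_maps: dict[str, dict[int, object]] = {}
    for col in df.columns[1:]:
        v = df[col].to_numpy()
        if not np.issubdtype(v.dtype, np.integer):
            if np.any(v != np.floor(v)):
                raise ValueError(f"covariate {col!r} must be integer-coded")
            v = v.astype(np.int64)
        levels = np.unique(v)
        if not np.array_equal(levels, np.arange(1, levels.size + 1)):
            mapping = {int(orig): new for new, orig in enumerate(levels, start=1)}
            log.info("re-indexing design column %r levels: %s", col, mapping)
            v = np.array([mapping[int(x)] for x in v], dtype=np.int64)
            level_maps[str(col)] = {new: orig for orig, new in mapping.items()}
        df[col] = v
    return DesignMatrix(df, level_maps=level_maps)


def write_design(design: DesignMatrix, path) -> None:
    path = Path(path)
    design.table.to_csv(path, sep="\t" if path.suffix.lower() != ".csv" else ",", index=False)


@dataclass
class RunConfig:
    """Fully serializable description of one fit run."""

    counts_path: str
    design_path: str
    protein: str
    isotype: str
    out_dir: str
    priors: dict = field(default_factory=dict)  # PriorConfig field overrides
    tune_rhosq: bool = True
    chains: int = 4
    iter_warmup: int = 3000
    iter_sampling: int = 1000
    seed: int = 0
    allow_unconverged: bool = False
    log_level: str = "INFO"

    def prior_config(self) -> PriorConfig:
        return PriorConfig(**self.priors)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_fit_command(config: RunConfig) -> int:
    """Orchestrate one fit: read inputs, sample, write artifacts.

    Writes the posterior sample CSV, diagnostics TSV, an effect-summary JSON
    (for two-level single-covariate designs), the resolved config, and a
    stage-timing log.  Returns 0 only if the fit converged or
    ``allow_unconverged`` is set; 2 for missing inputs; 1 for stage failures.
    """
    from .analysis import log2fc_posterior
    from .inference import IsotypeGPRegressor

    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0
                log.info("stage %s finished in %.2fs", name, timings[name])

        return _T()

    try:
        with stage("read"):
            panel = read_counts(config.counts_path)
            design = read_design(config.design_path)
            protein = panel.column(config.protein)
            igg = panel.column(config.isotype)
    except FileNotFoundError as exc:
        log.error("stage read failed: %s", exc)
        return 2
    except Exception as exc:  # noqa: BLE001
        log.error("stage read failed: %s", exc)
        return 1

    try:
        with stage("fit"):
            est = IsotypeGPRegressor(
                priors=config.prior_config(),
                tune_rhosq=config.tune_rhosq,
                chains=config.chains,
                iter_warmup=config.iter_warmup,
                iter_sampling=config.iter_sampling,
                seed=config.seed,
            ).fit(design, protein, igg=igg)
        with stage("write"):
            est.result_.write_cond_samples(out / "posterior_samples.csv")
            est.result_.write_diagnostics(out / "diagnostics.tsv")
            config.to_yaml(out / "config.yaml")
            labels = est.combination_labels_
            summary = {
                "converged": bool(est.result_.converged),
                "divergences": int(est.result_.divergences),
                "combination_labels": labels,
                "rhosq_prior_upper": est.priors_.rhosq_hi,
                "timings_s": timings,
            }
            if len(labels) == 2:
                eff = log2fc_posterior(est.cond_means_, labels[1], labels[0], labels=labels)
                summary["log2fc"] = {
                    "comparison": f"{labels[1]} vs {labels[0]}",
                    "posterior_mean": eff.posterior_mean,
                    "posterior_median": eff.posterior_median,
                    "ci95": list(eff.central_interval(0.95)),
                    "pseudo_p": eff.pseudo_p,
                }
            (out / "effect_summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as exc:  # noqa: BLE001
        log.error("stage fit/write failed: %s", exc)
        return 1

    if not est.result_.converged and not config.allow_unconverged:
        log.error("fit did not converge (max Rhat > 1.01 or ESS < 100)")
        return 1
    return 0
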
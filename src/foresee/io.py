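"""File formats, run configuration, and the end-to-end pipeline.

The pipeline is organised around the three outsourcing roles: the data
owner holds plaintext counts, filters monomorphic SNPs, and encrypts;
the cloud evaluates the chi-square circuit on ciphertexts only; the
authorized user decrypts (and, in errorless mode, decodes) the released
values.  ``run_pipeline`` executes the three phases explicitly and
logs the effective parameters, including the analytic relative-error
bound for approximate runs.

Formats are plain TSV throughout: a counts table (snp_id, O11, O12,
O21, O22), a genotype matrix (SNPs x individuals with a group-label
header row), and a results table with per-cutoff significance columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .approx_div import build_plan
from .exceptions import InputError, ParameterError
from .gwas_chi2 import (
    DEFAULT_CUTOFFS,
    Chi2Result,
    SNPCounts,
    approx_relative_error_bound,
    build_chi2_lookup,
    chi2_equal_groups,
    chi2_general,
    chi2_pvalue,
    secure_chi2_approx,
    secure_chi2_errorless,
)
from .he_sim import CostReport, HESession
from .modmath import smallest_prime_above
from .synthdata import Cohort

logger = logging.getLogger("foresee")

__all__ = [
    "RunConfig",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "read_vcf",
    "write_results_tsv",
    "read_results_tsv",
    "read_config",
    "resolve_parameters",
    "run_pipeline",
]

COUNT_COLUMNS = ["snp_id", "O11", "O12", "O21", "O22"]


@dataclass(frozen=True)
class RunConfig:
    """Effective parameters of one pipeline run."""

    mode: str  # exact | approx | errorless
    n: int | None = None
    p: int | None = None
    M: int | None = None
    n_slots: int = 864
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    input_path: str | None = None
    output_path: str | None = None
    cost_report_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("exact", "approx", "errorless"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.n_slots < 1:
            raise InputError("n_slots must be >= 1")


# ---------------------------------------------------------------------------
# TSV / VCF formats
# ---------------------------------------------------------------------------

def read_counts_tsv(
    path: str | Path, require_equal_totals: bool = False
) -> list[SNPCounts]:
    """Read a per-SNP allele-count table.

    ``require_equal_totals`` enforces N1 == N2 across all rows — the
    precondition of the encrypted (equal-group) pipelines.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty and df.columns.size == 0:
        logger.warning("counts file %s is empty", path)
        return []
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"counts file {path} lacks columns {missing}")
    out = []
    for _, row in df.iterrows():
        try:
            rec = SNPCounts(
                str(row["snp_id"]),
                int(row["O11"]),
                int(row["O12"]),
                int(row["O21"]),
                int(row["O22"]),
            )
        except (ValueError, TypeError) as exc:
            raise InputError(f"malformed counts row {row.to_dict()}: {exc}") from exc
        out.append(rec)
    if require_equal_totals:
        for rec in out:
            if rec.n1 != rec.n2:
                raise InputError(
                    f"SNP {rec.snp_id}: group totals differ ({rec.n1} != {rec.n2}); "
                    f"the encrypted pipelines require equal groups"
                )
    return out


def write_counts_tsv(counts: Sequence[SNPCounts], path: str | Path) -> None:
    pd.DataFrame(
        [(c.snp_id, c.o11, c.o12, c.o21, c.o22) for c in counts],
        columns=COUNT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_genotypes_tsv(cohort: Cohort, path: str | Path,
                        truth_path: str | Path | None = None) -> None:
    """Genotype matrix as TSV: header row carries group labels; a
    leading comment records the generator seed for reproducibility."""
    S, N = cohort.genotypes.shape
    cols = [f"{g}_{i}" for i, g in enumerate(cohort.groups)]
    df = pd.DataFrame(cohort.genotypes, columns=cols)
    df.insert(0, "snp_id", [f"snp{i}" for i in range(S)])
    with open(path, "w") as fh:
        fh.write(f"# foresee synthetic cohort seed={cohort.spec.seed} "
                 f"n={cohort.spec.n} n_snps={cohort.spec.n_snps}\n")
        df.to_csv(fh, sep="\t", index=False)
    if truth_path is not None:
        pd.DataFrame(
            {"snp_id": df["snp_id"], "associated": cohort.truth.astype(int)}
        ).to_csv(truth_path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path):
    """Returns (genotype matrix, group labels, snp ids)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "snp_id" not in df.columns:
        raise InputError(f"genotype file {path} lacks an snp_id column")
    snp_ids = df["snp_id"].astype(str).tolist()
    sample_cols = [c for c in df.columns if c != "snp_id"]
    groups = []
    for c in sample_cols:
        label = c.rsplit("_", 1)[0].lower()
        if label not in ("case", "control"):
            raise InputError(
                f"genotype column {c!r} does not encode a case/control label"
            )
        groups.append(label)
    G = df[sample_cols].to_numpy()
    return G, groups, snp_ids


def read_vcf(vcf_path: str | Path, groups_tsv: str | Path):
    """Genotypes from a VCF (biallelic records, GT field) plus a
    two-column sample-to-group TSV.  Returns (matrix, groups, snp_ids).

    Missing or half-called genotypes are rejected, matching the
    complete-data assumption of the counting step.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise InputError("VCF input requires the cyvcf2 package") from exc
    mapping = pd.read_csv(groups_tsv, sep="\t", header=None,
                          names=["sample", "group"])
    group_of = dict(zip(mapping["sample"].astype(str),
                        mapping["group"].astype(str).str.lower()))
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in group_of]
    if unknown:
        raise InputError(f"samples without group labels: {unknown}")
    rows, snp_ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise InputError(
                f"record {var.ID or var.POS} is not biallelic"
            )
        gts = []
        for a, b, *_ in var.genotypes:
            if a < 0 or b < 0:
                raise InputError(
                    f"missing genotype at {var.ID or var.POS}; "
                    f"complete data are required"
                )
            gts.append(int(a > 0) + int(b > 0))
        rows.append(gts)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    groups = [group_of[s] for s in samples]
    return np.asarray(rows, dtype=np.int8), groups, snp_ids


def write_results_tsv(
    results: Sequence[Chi2Result],
    path: str | Path,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> None:
    rows = []
    for r in results:
        row = {
            "snp_id": r.snp_id,
            "chi2_exact": r.chi2_exact,
            "chi2_protocol": r.chi2_protocol,
            "pvalue": r.pvalue,
        }
        for cut in cutoffs:
            row[f"significant_{cut:g}"] = (
                int(r.pvalue < cut) if r.pvalue is not None else ""
            )
        row["flag"] = "monomorphic" if r.monomorphic else "ok"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a plain ``key = value`` config file; keyword overrides win.

    Recognized keys mirror the CLI flags: mode, n, p, M, n_slots,
    cutoffs (comma-separated), input, output, cost_report, seed.
    """
    raw: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
    kwargs: dict = {}
    if "mode" in raw:
        kwargs["mode"] = raw["mode"]
    for key in ("n", "p", "M", "n_slots", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "cutoffs" in raw:
        kwargs["cutoffs"] = tuple(float(x) for x in raw["cutoffs"].split(","))
    for src, dst in (("input", "input_path"), ("output", "output_path"),
                     ("cost_report", "cost_report_path")):
        if src in raw:
            kwargs[dst] = raw[src]
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    if "mode" not in kwargs:
        raise InputError(f"config {path} does not set a mode")
    return RunConfig(**kwargs)


def resolve_parameters(config: RunConfig, n: int) -> RunConfig:
    """Fill mode-dependent defaults for (p, M) given the group size.

    Approximate mode: if only p is given, M = p - 1 (the scale rule
    M = min(p-1, (p-1)/max(A/B)) with max A/B = 1 over the feasible
    region); if neither is given, M = 4n^2 * 10^6 — a 10^-6 relative-
    error budget — and p is the smallest prime above M.  Errorless
    mode: p defaults to the injectivity-safe prime for statistic-scale
    fractions (a user-supplied smaller p is vetted at table build).
    """
    cfg = config if config.n is not None else replace(config, n=n)
    if cfg.n != n:
        raise ParameterError(
            f"configured n={cfg.n} but the data imply n={n} individuals per group"
        )
    if cfg.mode == "approx":
        p, M = cfg.p, cfg.M
        if p is None and M is None:
            M = 4 * n * n * 10**6
            p = smallest_prime_above(M)
        elif p is not None and M is None:
            M = p - 1
        elif p is None:
            p = smallest_prime_above(M)
        if p <= M:
            raise ParameterError(f"approx mode requires p > M (got p={p}, M={M})")
        cfg = replace(cfg, p=p, M=M)
    return cfg


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _batched(seq: Sequence, size: int):
    for i in range(0, len(seq), size):
        yield seq[i : i + size]


def run_pipeline(
    config: RunConfig, counts: Sequence[SNPCounts] | None = None
) -> tuple[list[Chi2Result], CostReport]:
    """Execute owner-encrypt -> cloud-compute -> user-decode.

    ``counts`` may be passed directly; otherwise they are read from
    ``config.input_path``.  SNPs are processed in ceil(S / n_slots)
    ciphertext batches; monomorphic SNPs are flagged and excluded from
    the encrypted phases (the data owner holds plaintext and filters
    them before encryption).
    """
    if counts is None:
        if config.input_path is None:
            raise InputError("no counts provided and no input path configured")
        counts = read_counts_tsv(
            config.input_path, require_equal_totals=config.mode != "exact"
        )
    results: list[Chi2Result | None] = [None] * len(counts)

    if config.mode == "exact":
        for i, rec in enumerate(counts):
            if rec.monomorphic:
                results[i] = Chi2Result(rec.snp_id, None, None, None, True)
                continue
            if rec.n1 == rec.n2 and rec.n1 % 2 == 0:
                stat = float(chi2_equal_groups(rec.o11, rec.o21, rec.n1 // 2))
            else:
                stat = chi2_general(rec)
            results[i] = Chi2Result(rec.snp_id, stat, None, chi2_pvalue(stat), False)
        report = CostReport(0, 0, 0, 0)
    else:
        n_vals = {rec.n1 for rec in counts} | {rec.n2 for rec in counts}
        if len(n_vals) != 1:
            raise InputError("encrypted modes require one common group size")
        (total,) = n_vals
        if total % 2:
            raise InputError(f"allele total {total} is odd; expected 2n")
        n = total // 2
        cfg = resolve_parameters(config, n)
        live = [(i, rec) for i, rec in enumerate(counts) if not rec.monomorphic]
        for i, rec in enumerate(counts):
            if rec.monomorphic:
                results[i] = Chi2Result(rec.snp_id, None, None, None, True)

        if cfg.mode == "approx":
            plan = build_plan(n, cfg.p, cfg.M)
            logger.info(
                "approx run: n=%d p=%d M=%d d=%d C=%d L_s=%d rel-err bound %.3g%%",
                n, cfg.p, cfg.M, plan.d, plan.C, cfg.n_slots,
                100 * approx_relative_error_bound(n, cfg.M),
            )
            session = HESession(cfg.p, n_slots=cfg.n_slots)
            runner = lambda o11s, o21s, ids: secure_chi2_approx(
                o11s, o21s, n, plan, session=session, snp_ids=ids
            )
        else:
            lookup = build_chi2_lookup(n, cfg.p)
            logger.info(
                "errorless run: n=%d p=%d table=%d entries L_s=%d",
                n, lookup.p, len(lookup), cfg.n_slots,
            )
            session = HESession(lookup.p, n_slots=cfg.n_slots)
            runner = lambda o11s, o21s, ids: secure_chi2_errorless(
                o11s, o21s, n, lookup=lookup, session=session, snp_ids=ids
            )

        for batch in _batched(live, cfg.n_slots):
            ids = [rec.snp_id for _, rec in batch]
            o11s = [rec.o11 for _, rec in batch]
            o21s = [rec.o21 for _, rec in batch]
            for (i, _), res in zip(batch, runner(o11s, o21s, ids)):
                results[i] = res
        report = session.cost_report()

    final = [r for r in results if r is not None]
    if config.output_path:
        write_results_tsv(final, config.output_path, config.cutoffs)
    if config.cost_report_path:
        with open(config.cost_report_path, "w") as fh:
            json.dump(report.as_dict(), fh, indent=2)
    return final, report
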
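"""Per-assembly summaries, the EVE-count linear model, benchmark metrics.

Summaries tabulate, per assembly, the scaffolds carrying only an RdRp
EVE, only an MCP EVE, or both gene classes; a scaffold with both
classes is counted once, in the "both" column, so category counts sum
to the total number of EVE-containing scaffolds.

The count model is an ordinary least-squares fit of EVE-containing
scaffold counts on dinoflagellate genus plus assembly-quality
covariates (query length, N50, completeness), with type-II F tests per
term and all pairwise genus contrasts.  Contrast p-values are adjusted
with Tukey's HSD (studentized-range) by default; Holm is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range
from statsmodels.stats.multitest import multipletests

from .core import InputError
from .evecall import EveCall
from .synthio import GroundTruthManifest


@dataclass(frozen=True)
class GenomeSummary:
    assembly: str
    genus: str = ""
    family: str = ""
    rdrp_only: int = 0
    mcp_only: int = 0
    both: int = 0
    total_length: float = float("nan")
    n50: float = float("nan")
    completeness: float = float("nan")

    @property
    def total(self) -> int:
        """EVE-containing scaffolds (each counted once)."""
        return self.rdrp_only + self.mcp_only + self.both


def summarize(
    calls: Sequence[EveCall],
    metadata: Mapping[str, Mapping[str, object]],
    scaffold_assembly: Mapping[str, str],
) -> list[GenomeSummary]:
    """Per-assembly scaffold counts by EVE gene-class category.

    ``scaffold_assembly`` maps scaffold ids to assembly ids;
    ``metadata`` maps assembly ids to genus/family/metrics entries.
    """
    per_scaffold: dict[str, set[str]] = {}
    for c in calls:
        classes = per_scaffold.setdefault(c.scaffold_id, set())
        for m in c.members:
            classes.add(m.gene_class)
        if c.scaffold_id not in scaffold_assembly:
            raise InputError(f"call on unknown scaffold {c.scaffold_id!r}")
    counts: dict[str, dict[str, int]] = {
        a: {"rdrp_only": 0, "mcp_only": 0, "both": 0} for a in metadata
    }
    for sid, classes in per_scaffold.items():
        assembly = scaffold_assembly[sid]
        if assembly not in counts:
            raise InputError(f"scaffold {sid!r} maps to unknown assembly {assembly!r}")
        if "MCP" in classes and "RdRp" in classes:
            counts[assembly]["both"] += 1
        elif "RdRp" in classes:
            counts[assembly]["rdrp_only"] += 1
        else:
            counts[assembly]["mcp_only"] += 1
    out = []
    for assembly, meta in metadata.items():
        out.append(
            GenomeSummary(
                assembly=assembly,
                genus=str(meta.get("genus", "")),
                family=str(meta.get("family", "")),
                rdrp_only=counts[assembly]["rdrp_only"],
                mcp_only=counts[assembly]["mcp_only"],
                both=counts[assembly]["both"],
                total_length=float(meta.get("total_length", float("nan"))),
                n50=float(meta.get("n50", float("nan"))),
                completeness=float(meta.get("completeness", float("nan"))),
            )
        )
    return out


def rollup(summaries: Iterable[GenomeSummary]) -> pd.DataFrame:
    """Family-level totals of EVE-containing scaffolds."""
    df = summaries_frame(summaries)
    return (
        df.groupby("family", dropna=False)[["rdrp_only", "mcp_only", "both", "total"]]
        .sum()
        .reset_index()
    )


def summaries_frame(summaries: Iterable[GenomeSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "assembly": s.assembly,
                "genus": s.genus,
                "family": s.family,
                "rdrp_only": s.rdrp_only,
                "mcp_only": s.mcp_only,
                "both": s.both,
                "total": s.total,
                "total_length": s.total_length,
                "n50": s.n50,
                "completeness": s.completeness,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# count model


@dataclass
class CountModelFit:
    coefficients: pd.DataFrame  # estimate, se, t, p per coefficient
    anova: pd.DataFrame  # type-II F tests per term
    contrasts: pd.DataFrame  # pairwise genus contrasts, adjusted p
    residual_df: int
    model: object = field(repr=False, default=None)


def fit_count_model(
    data: pd.DataFrame,
    response: str = "total",
    covariates: Sequence[str] = ("total_length", "n50", "completeness"),
    adjust: str = "tukey",
) -> CountModelFit:
    """OLS of EVE-scaffold counts on genus + assembly-quality covariates."""
    needed = {response, "genus", *covariates}
    missing = needed - set(data.columns)
    if missing:
        raise InputError(f"count model input lacks columns: {sorted(missing)}")
    genera = sorted(data["genus"].unique())
    if len(genera) < 2:
        raise InputError("count model needs >= 2 genera")
    covariates = [c for c in covariates]
    formula = f"{response} ~ C(genus)" + "".join(f" + {c}" for c in covariates)
    model = smf.ols(formula, data=data).fit()
    exog = model.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # locate offending columns by incremental rank
        names = model.model.exog_names
        bad = []
        for k in range(1, exog.shape[1] + 1):
            if np.linalg.matrix_rank(exog[:, :k]) < k:
                bad.append(names[k - 1])
        raise InputError(f"count model design is rank deficient: {bad}")
    if model.df_resid <= 0:
        raise InputError("count model has no residual degrees of freedom")
    coeffs = pd.DataFrame(
        {
            "estimate": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    )
    if model.ssr <= 1e-12:
        anova = pd.DataFrame(
            {"F": np.zeros(0), "PR(>F)": np.zeros(0)}
        )
    else:
        anova = sm.stats.anova_lm(model, typ=2)
    contrasts = _genus_contrasts(model, genera, adjust)
    return CountModelFit(
        coefficients=coeffs,
        anova=anova,
        contrasts=contrasts,
        residual_df=int(model.df_resid),
        model=model,
    )


def _genus_contrasts(model, genera: Sequence[str], adjust: str) -> pd.DataFrame:
    names = model.model.exog_names
    k = len(genera)
    df_resid = model.df_resid

    def coef_vector(genus: str) -> np.ndarray:
        v = np.zeros(len(names))
        col = f"C(genus)[T.{genus}]"
        if col in names:
            v[names.index(col)] = 1.0
        return v

    rows = []
    for a, b in itertools.combinations(genera, 2):
        c = coef_vector(a) - coef_vector(b)
        res = model.t_test(c)
        est = float(np.asarray(res.effect).ravel()[0])
        se = float(np.asarray(res.sd).ravel()[0])
        t = float(np.asarray(res.tvalue).ravel()[0])
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se, "t": t})
    out = pd.DataFrame(rows)
    if adjust == "tukey":
        out["p_adj"] = [
            float(studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_resid))
            for t in out["t"]
        ]
    elif adjust == "holm":
        from scipy.stats import t as tdist

        raw = 2.0 * tdist.sf(np.abs(out["t"]), df_resid)
        out["p_adj"] = multipletests(raw, method="holm")[1]
    else:
        raise InputError(f"unknown adjustment {adjust!r} (tukey or holm)")
    return out


# ---------------------------------------------------------------------------
# benchmark evaluation


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return inter / max(1, b[1] - b[0])


def benchmark_eval(
    calls: Sequence[EveCall],
    truth: GroundTruthManifest,
    min_overlap: float = 0.5,
    divergence_bins: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.51),
    pairing_threshold_nt: int = 1500,
) -> pd.DataFrame:
    """Recovery metrics of calls against the planted ground truth.

    A planted viral member counts as recovered when a call member of
    the same gene class on the same scaffold covers at least
    ``min_overlap`` of the planted interval.  Precision is the fraction
    of called members overlapping some planted viral feature.  A
    planted genomic pair (gap within the pairing threshold) counts as
    recovered only when a genomic call pairs its two members.
    """
    truth_scaffolds = {r.scaffold_id for r in truth.records}
    for c in calls:
        if c.scaffold_id not in truth_scaffolds:
            raise InputError(
                f"benchmark_eval: call on scaffold {c.scaffold_id!r} absent "
                "from the ground-truth manifest"
            )
    members = [(c, m) for c in calls for m in c.members]
    truths = truth.viral_members()

    def recovered(rec) -> bool:
        return any(
            m.scaffold_id == rec.scaffold_id
            and m.gene_class == rec.feature
            and _overlap_frac(m.interval, (rec.start, rec.end)) >= min_overlap
            for _, m in members
        )

    def member_is_true(m) -> bool:
        return any(
            rec.scaffold_id == m.scaffold_id
            and rec.feature == m.gene_class
            and _overlap_frac((rec.start, rec.end), m.interval) >= min_overlap
            for rec in truths
        )

    rows = []

    def add_row(label: str, recs: Sequence) -> None:
        tp = sum(recovered(r) for r in recs)
        sens = tp / len(recs) if recs else float("nan")
        rows.append({"subset": label, "n": len(recs), "sensitivity": sens})

    add_row("overall", truths)
    bins = list(divergence_bins)
    for lo, hi in zip(bins[:-1], bins[1:]):
        add_row(
            f"divergence_{lo:.2f}_{hi:.2f}",
            [r for r in truths if lo <= r.divergence < hi],
        )
    metrics = pd.DataFrame(rows)
    n_called = len(members)
    n_true_calls = sum(member_is_true(m) for _, m in members)
    precision = n_true_calls / n_called if n_called else float("nan")
    metrics["precision"] = precision
    metrics["f1"] = (
        2 * metrics["sensitivity"] * precision / (metrics["sensitivity"] + precision)
    ).where((metrics["sensitivity"] + precision) > 0)

    # genomic-pair recovery
    pairs = [p for p in truth.genomic_pairs() if (p.gap or 0) <= pairing_threshold_nt]
    pair_hits = 0
    for p in pairs:
        mem = [
            r
            for r in truth.for_scaffold(p.scaffold_id)
            if r.group == p.group and r.feature in ("MCP", "RdRp")
        ]
        for c in calls:
            if c.scaffold_id != p.scaffold_id or c.type != "genomic":
                continue
            ok = all(
                any(
                    m.gene_class == r.feature
                    and _overlap_frac(m.interval, (r.start, r.end)) >= min_overlap
                    for m in c.members
                )
                for r in mem
            )
            if ok:
                pair_hits += 1
                break
    metrics.attrs["genomic_pairs_planted"] = len(pairs)
    metrics.attrs["genomic_pairs_recovered"] = pair_hits
    return metrics
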
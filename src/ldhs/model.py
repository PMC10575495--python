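"""Model/Results front-end over the locus-driven harmony search.

``LocusDrivenHarmonySearch`` is constructed from a genotype dataset (and
optional annotations); ``fit()`` runs the search and returns
``LDHSResults``, which carries the verified candidate interactions, their
objective scores and significance tests, and renders a summary table.
"""

from __future__ import annotations

import io

import pandas as pd

from .genotype_data import AnnotationTable, GenotypeDataset, read_annotations, read_genotypes
from .harmony_search import SearchConfig, SearchResult, run_ldhs


class LocusDrivenHarmonySearch:
    """Locus-driven multi-population harmony search over a case-control dataset.

    Parameters
    ----------
    dataset
        Case-control genotype matrix.
    annotations
        SNP annotation table supplying locus groups and functional
        categories; ``None`` disables locus-driven initialization for lack
        of information (all SNPs fall in the lower-prior category).
    **params
        Any :class:`~ldhs.harmony_search.SearchConfig` field
        (``k``, ``hms``, ``hmcr``, ``par``, ``w``, ``locus_fraction``,
        ``max_evals``, ``alpha``, ...).
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        annotations: AnnotationTable | None = None,
        **params,
    ):
        self.dataset = dataset
        self.annotations = annotations
        self.params = params

    @classmethod
    def from_files(
        cls, genotype_path, annotation_path=None, dialect: str = "gametes_tsv", **params
    ) -> "LocusDrivenHarmonySearch":
        dataset = read_genotypes(genotype_path, dialect=dialect)
        annotations = read_annotations(annotation_path) if annotation_path else None
        return cls(dataset, annotations, **params)

    def fit(self, seed: int | None = None) -> "LDHSResults":
        """Run the search; ``seed`` overrides the configured RNG seed."""
        params = dict(self.params)
        if seed is not None:
            params["seed"] = seed
        config = SearchConfig(**params)
        result = run_ldhs(self.dataset, self.annotations, config)
        return LDHSResults(self, config, result)


class LDHSResults:
    """Fitted results: verified candidate SNP sets with scores and tests."""

    def __init__(self, model: LocusDrivenHarmonySearch, config: SearchConfig, result: SearchResult):
        self.model = model
        self.config = config
        self.result = result

    @property
    def candidates(self):
        """Significant candidate records, sorted by G-test p-value."""
        return self.result.candidates

    @property
    def eval_count(self) -> int:
        return self.result.eval_count

    def to_frame(self, significant_only: bool = False) -> pd.DataFrame:
        """Verified candidates as a DataFrame (one row per SNP set)."""
        records = self.result.candidates if significant_only else self.result.verified
        rows = []
        for rank, r in enumerate(records, start=1):
            rows.append(
                {
                    "rank": rank,
                    "snp_ids": ",".join(r.snp_ids),
                    "k2": r.scores.k2,
                    "lr": r.scores.lr,
                    "js": r.scores.js,
                    "ndje": r.scores.ndje,
                    "g_stat": r.test.g_statistic,
                    "g_pvalue": r.test.g_pvalue,
                    "chi2": r.test.chi2_statistic,
                    "chi2_pvalue": r.test.chi2_pvalue,
                    "significant": r.test.significant,
                }
            )
        return pd.DataFrame(rows)

    def summary(self, top: int = 10) -> str:
        """Human-readable summary of the run and its top candidates."""
        d = self.model.dataset
        buf = io.StringIO()
        buf.write("Locus-Driven Harmony Search Results\n")
        buf.write("=" * 67 + "\n")
        buf.write(
            f"Samples: {d.n_samples} ({d.n_case} cases / {d.n_control} controls)   "
            f"SNPs: {d.m}   order k: {self.config.k}\n"
        )
        buf.write(
            f"HMS: {self.config.hms}  HMCR: {self.config.hmcr}  PAR: {self.config.par}  "
            f"w: {self.config.w}  locus fraction: {self.config.locus_fraction}\n"
        )
        n_ver = len(self.result.verified)
        buf.write(
            f"Unique evaluations: {self.result.eval_count}   verified sets: {n_ver}   "
            f"significant: {len(self.result.candidates)} "
            f"(Bonferroni alpha = {self.config.alpha}/{n_ver})\n"
        )
        buf.write("-" * 67 + "\n")
        df = self.to_frame(significant_only=True).head(top)
        if df.empty:
            buf.write("No SNP set passed the corrected significance threshold.\n")
        else:
            with pd.option_context("display.width", 120, "display.float_format", "{:.4g}".format):
                buf.write(
                    df[["rank", "snp_ids", "k2", "lr", "js", "ndje", "g_pvalue", "chi2_pvalue"]]
                    .to_string(index=False)
                )
                buf.write("\n")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<LDHSResults: {len(self.result.candidates)} significant candidates, "
            f"{self.result.eval_count} evaluations>"
        )
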
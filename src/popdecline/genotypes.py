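"""Genotype containers, readers/writers and panel QC.

The central container is :class:`GenotypeMatrix`: an individuals x loci
matrix of diploid allele dosages (0, 1, 2 copies of the counted allele,
``MISSING`` = -1) with sample, population and locus labels.  A
:class:`LinkageMap` carries per-locus chromosome, physical position (bp)
and sex-averaged genetic position (Morgans); :class:`PopulationMeta`
carries the per-population metadata (continent, latitude, sampling year,
optional decline status) used downstream.

QC mirrors a standard SNP-array pipeline: a minor-allele-frequency cut
(strict ``MAF > threshold`` to keep a locus), a duplicate-sample screen
(zero mismatches at co-typed loci), and modal-genotype imputation of
missing calls.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING: int = -1

#: tokens recognised as missing in delimited genotype matrices
DEFAULT_MISSING_TOKENS = frozenset({"NA", "-9", "."})


class EmptyPanelError(ValueError):
    """Raised when a filter removes every locus from a panel."""


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with sample/population/locus labels.

    Parameters
    ----------
    samples
        Sample identifiers, one per row.
    population_of
        Mapping sample id -> population id; every sample must be present.
    loci
        Locus identifiers, one per column, unique.
    dosage
        ``(n_samples, n_loci)`` int8 array with entries in
        ``{0, 1, 2, MISSING}`` counting copies of the counted allele.
    counted_allele
        Optional per-locus record of which allele is counted (VCF ALT by
        convention).
    """

    samples: list[str]
    population_of: dict[str, str]
    loci: list[str]
    dosage: np.ndarray
    counted_allele: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus ids are not unique")
        missing_pop = [s for s in self.samples if s not in self.population_of]
        if missing_pop:
            raise ValueError(f"samples without population: {missing_pop[:5]}")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosage[i, j]} at sample "
                f"{self.samples[i]}, locus {self.loci[j]}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.population_of[s], None)
        return list(seen)

    def population_labels(self) -> np.ndarray:
        """Per-row population id as an object array."""
        return np.array([self.population_of[s] for s in self.samples])

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return replace(
            self,
            samples=list(keep),
            population_of={s: self.population_of[s] for s in keep},
            dosage=self.dosage[idx, :].copy(),
        )

    def subset_populations(self, pops: list[str] | set[str]) -> "GenotypeMatrix":
        pops = set(pops)
        keep = [s for s in self.samples if self.population_of[s] in pops]
        return self.subset_samples(keep)

    def subset_loci(self, keep: list[str]) -> "GenotypeMatrix":
        pos = {l: j for j, l in enumerate(self.loci)}
        idx = [pos[l] for l in keep]
        return replace(
            self,
            loci=list(keep),
            dosage=self.dosage[:, idx].copy(),
            counted_allele={l: self.counted_allele[l] for l in keep if l in self.counted_allele},
        )

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per locus over non-missing calls (nan if none)."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class LinkageMap:
    """Per-locus chromosome, physical bp (1-based) and genetic position (Morgans)."""

    table: pd.DataFrame  # index = locus id; columns: chrom, bp, morgans

    def __post_init__(self) -> None:
        required = {"chrom", "bp", "morgans"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"linkage map needs columns {sorted(required)}")
        if (self.table["morgans"] < 0).any():
            raise ValueError("negative genetic position in linkage map")

    @property
    def loci(self) -> list[str]:
        return list(self.table.index)

    def has(self, locus: str) -> bool:
        return locus in self.table.index

    def chrom(self, locus: str) -> str:
        return self.table.at[locus, "chrom"]

    def subset(self, loci: list[str]) -> "LinkageMap":
        return LinkageMap(self.table.loc[loci].copy())

    def unmapped(self, loci: list[str]) -> list[str]:
        return [l for l in loci if l not in self.table.index]


@dataclass
class PopulationMeta:
    """Population-level metadata: continent, latitude, sampling year, decline status."""

    table: pd.DataFrame  # index = population id; columns: continent, latitude, year, [declining]

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate population ids in metadata")
        lat = self.table["latitude"]
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude outside [-90, 90]")

    def latitude_of(self, pop: str) -> float:
        return float(self.table.at[pop, "latitude"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(
    path,
    format: str = "matrix",
    *,
    metadata: pd.DataFrame | dict | None = None,
    missing_tokens=DEFAULT_MISSING_TOKENS,
) -> GenotypeMatrix:
    """Read a genotype panel from a VCF or a delimited dosage matrix.

    ``metadata`` supplies the sample -> population mapping: either a dict or
    a DataFrame with columns ``sample`` and ``population``.  Samples absent
    from the metadata are assigned population ``"unknown"``.
    """
    if format == "vcf":
        return _read_vcf(path, metadata)
    if format == "matrix":
        return _read_matrix(path, metadata, missing_tokens)
    raise ValueError(f"unknown genotype format: {format!r}")


def _pop_mapping(metadata, samples: list[str]) -> dict[str, str]:
    if metadata is None:
        return {s: "unknown" for s in samples}
    if isinstance(metadata, dict):
        return {s: metadata.get(s, "unknown") for s in samples}
    m = dict(zip(metadata["sample"], metadata["population"]))
    return {s: m.get(s, "unknown") for s in samples}


def _read_vcf(path, metadata) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    loci: list[str] = []
    counted: dict[str, str] = {}
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                f"({rec.ID or 'unnamed'}): only biallelic SNPs supported"
            )
        lid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        loci.append(lid)
        counted[lid] = rec.ALT[0]
        # gts012: 0/1/2 = ALT dosage, 3 = unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        cols.append(g)
    dosage = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), np.int8)
    )
    return GenotypeMatrix(
        samples=samples,
        population_of=_pop_mapping(metadata, samples),
        loci=loci,
        dosage=dosage,
        counted_allele=counted,
    )


def _read_matrix(path, metadata, missing_tokens) -> GenotypeMatrix:
    counted: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    lines = []
    for ln in text.splitlines():
        if ln.startswith("#counted_allele"):
            # header line: "#counted_allele locus=A locus2=C ..."
            for tok in ln.split()[1:]:
                lid, _, al = tok.partition("=")
                counted[lid] = al
        elif not ln.startswith("#"):
            lines.append(ln)
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", dtype=str)
    sample_col = df.columns[0]
    samples = df[sample_col].tolist()
    loci = list(df.columns[1:])
    dosage = np.empty((len(samples), len(loci)), dtype=np.int8)
    for j, locus in enumerate(loci):
        col = df[locus]
        for i, tok in enumerate(col):
            tok = str(tok).strip()
            if tok in missing_tokens or tok == "nan":
                dosage[i, j] = MISSING
            elif tok in ("0", "1", "2"):
                dosage[i, j] = int(tok)
            else:
                raise ValueError(
                    f"unknown genotype token {tok!r} at row {samples[i]}, "
                    f"column {locus}"
                )
    return GenotypeMatrix(
        samples=samples,
        population_of=_pop_mapping(metadata, samples),
        loci=loci,
        dosage=dosage,
        counted_allele=counted,
    )


def write_genotype_matrix(G: GenotypeMatrix, path, *, header_comments=()) -> None:
    """Write a GenotypeMatrix as TSV (missing -> ``NA``); round-trips exactly."""
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        if G.counted_allele:
            toks = " ".join(f"{l}={a}" for l, a in G.counted_allele.items())
            fh.write(f"#counted_allele {toks}\n")
        fh.write("sample\t" + "\t".join(G.loci) + "\n")
        for i, s in enumerate(G.samples):
            row = ["NA" if g == MISSING else str(int(g)) for g in G.dosage[i]]
            fh.write(s + "\t" + "\t".join(row) + "\n")


def read_linkage_map(path) -> tuple[LinkageMap, list[str]]:
    """Read a linkage-map TSV.

    Two dialects are accepted: ``locus, chrom, bp, male_cM, female_cM``
    (genetic position = mean of the sexes, cM -> Morgans) or
    ``locus, chrom, bp, morgans`` (passes through unchanged).  Returns the
    map and the (initially empty) list of loci later found unmapped.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    if {"male_cM", "female_cM"}.issubset(df.columns):
        morgans = (df["male_cM"] + df["female_cM"]) / 2.0 / 100.0
    elif "morgans" in df.columns:
        morgans = df["morgans"].astype(float)
    else:
        raise ValueError(
            "linkage map needs either male_cM/female_cM or a morgans column"
        )
    table = pd.DataFrame(
        {"chrom": df["chrom"].astype(str), "bp": df["bp"].astype(np.int64), "morgans": morgans}
    )
    return LinkageMap(table), []


def write_linkage_map(lmap: LinkageMap, path) -> None:
    out = lmap.table.reset_index()
    out.columns = ["locus", "chrom", "bp", "morgans"]
    out.to_csv(path, sep="\t", index=False)


def write_population_meta(meta: PopulationMeta, path) -> None:
    out = meta.table.reset_index()
    out = out.rename(columns={out.columns[0]: "pop"})
    out.to_csv(path, sep="\t", index=False)


def read_population_meta(path) -> PopulationMeta:
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index("pop")
    return PopulationMeta(df)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_maf(
    G: GenotypeMatrix,
    threshold: float,
    scope: str = "global",
    *,
    groups: dict[str, str] | None = None,
    strict: bool = True,
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove loci failing the minor-allele-frequency cut.

    With ``strict`` (default) a locus is kept only if MAF > threshold,
    honouring an exclusive cutoff; ``strict=False`` keeps MAF >= threshold.
    ``scope='per-group'`` computes MAF within each group of populations
    (``groups`` maps population id -> group label; default: each population
    is its own group) and keeps loci passing in every group.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")

    def passes(sub: GenotypeMatrix) -> np.ndarray:
        maf = sub.minor_allele_freq()
        maf = np.where(np.isnan(maf), 0.0, maf)
        return maf > threshold if strict else maf >= threshold

    if scope == "global":
        keep_mask = passes(G)
    elif scope == "per-group":
        poplab = G.population_labels()
        if groups is None:
            group_of = {p: p for p in G.populations}
        else:
            group_of = groups
        keep_mask = np.ones(G.n_loci, dtype=bool)
        for grp in sorted(set(group_of.values())):
            pops = [p for p, g in group_of.items() if g == grp]
            rows = np.isin(poplab, pops)
            if not rows.any():
                continue
            sub = replace(
                G,
                samples=[s for s, r in zip(G.samples, rows) if r],
                population_of={s: G.population_of[s] for s, r in zip(G.samples, rows) if r},
                dosage=G.dosage[rows, :],
            )
            keep_mask &= passes(sub)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    removed = [l for l, k in zip(G.loci, keep_mask) if not k]
    kept = [l for l, k in zip(G.loci, keep_mask) if k]
    if not kept:
        raise EmptyPanelError(
            f"MAF filter at {threshold} removed all {G.n_loci} loci"
        )
    return G.subset_loci(kept), removed


def find_duplicate_samples(G: GenotypeMatrix):
    """Pairs of samples with identical genotypes at every co-typed locus.

    Returns ``(duplicates, uninformative)``: each duplicate is
    ``(sample_a, sample_b, n_compared)``; pairs with zero comparable loci
    are listed separately as uninformative, not duplicates.
    """
    if G.n_samples < 2:
        raise ValueError("need at least two samples")
    D = G.dosage
    present = D != MISSING
    duplicates = []
    uninformative = []
    for i in range(G.n_samples):
        for j in range(i + 1, G.n_samples):
            both = present[i] & present[j]
            n = int(both.sum())
            if n == 0:
                uninformative.append((G.samples[i], G.samples[j]))
                continue
            if np.array_equal(D[i][both], D[j][both]):
                duplicates.append((G.samples[i], G.samples[j], n))
    return duplicates, uninformative


def impute_most_frequent(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace every missing call with the modal dosage class of its locus.

    Ties between dosage classes break to the lowest class, so the result
    is deterministic and independent of sample order.  A locus with no
    observed genotypes at all is an error.
    """
    D = G.dosage.copy()
    for j in range(G.n_loci):
        col = D[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(f"locus {G.loci[j]} is entirely missing; cannot impute")
        counts = np.bincount(obs, minlength=3)
        col[miss] = int(np.argmax(counts))  # argmax takes lowest class on ties
    return replace(G, dosage=D)
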
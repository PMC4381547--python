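"""Data model, TSV readers/writers, genotype QC and de-regression.

The package works on four tables: a pedigree (id, sire, dam), a biallelic
SNP genotype matrix coded as counted-allele dosages 0/1/2 with a marker map
(chromosome, bp), a trait table of predicted transmitting abilities (PTA)
with per-individual reliabilities, and an optional BED-like annotation of
reported QTL intervals.

Conventions
-----------
* Unknown parents are the sentinel ``"0"``.
* Genomic coordinates are 1-based inclusive on disk and converted to
  0-based half-open in memory.
* Missing genotype calls are ``NaN`` in the float dosage matrix; after QC
  and imputation no missing entries remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

AUTOSOMES = set(range(1, 30))


class ParseError(ValueError):
    """A file failed to parse; message names the file and offending line."""


class ValidationError(ValueError):
    """In-memory data violated a type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Marker identifiers with genomic coordinates.

    ``chromosome`` holds integer autosome labels (1-29) or the strings
    ``"unmapped"`` / ``"sex"``; ``position_bp`` is the 0-based position.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if len(set(self.marker_id)) != len(self.marker_id):
            raise ValidationError("duplicate marker ids in map")
        if np.any(self.position_bp < 0):
            raise ValidationError("negative marker position")

    def __len__(self) -> int:
        return len(self.marker_id)

    def is_autosomal(self) -> np.ndarray:
        return np.array(
            [isinstance(c, (int, np.integer)) and int(c) in AUTOSOMES
             for c in self.chromosome],
            dtype=bool,
        )

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.marker_id[idx], self.chromosome[idx],
                         self.position_bp[idx])


@dataclass
class GenotypeMatrix:
    """n x m counted-allele dosage matrix with its marker map.

    ``calls`` is float with entries in {0, 1, 2, NaN}.  ``imputed`` flags
    calls that were filled in by :func:`impute_mode`.
    """

    individual_ids: list
    calls: np.ndarray
    map: MarkerMap
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.float64)
        n, m = self.calls.shape
        if len(self.individual_ids) != n:
            raise ValidationError("individual_ids do not match matrix rows")
        if len(self.map) != m:
            raise ValidationError("marker map does not match matrix columns")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual ids")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValidationError(
                f"genotype entry {self.calls[tuple(bad)]!r} at row {bad[0]}, "
                f"column {bad[1]} is not in {{0,1,2,missing}}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per marker, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0


@dataclass
class Pedigree:
    """Parentage records; guaranteed acyclic and topologically ordered.

    ``ids``, ``sires`` and ``dams`` are parallel object arrays with
    :data:`UNKNOWN_PARENT` for unknown parents.  Construction re-orders the
    records so that parents always precede offspring and raises on cycles.
    """

    ids: np.ndarray
    sires: np.ndarray
    dams: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.sires = np.asarray(self.sires, dtype=object)
        self.dams = np.asarray(self.dams, dtype=object)
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate ids in pedigree")
        order = self._toposort()
        self.ids = self.ids[order]
        self.sires = self.sires[order]
        self.dams = self.dams[order]

    def _toposort(self) -> np.ndarray:
        pos = {i: k for k, i in enumerate(self.ids)}
        state = np.zeros(len(self.ids), dtype=np.int8)  # 0 new 1 open 2 done
        order: list[int] = []
        for root in range(len(self.ids)):
            if state[root]:
                continue
            stack = [(root, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    state[node] = 2
                    order.append(node)
                    continue
                if state[node] == 2:
                    continue
                if state[node] == 1:
                    raise ValidationError(
                        f"pedigree cycle involving id {self.ids[node]!r}")
                state[node] = 1
                stack.append((node, True))
                for parent in (self.sires[node], self.dams[node]):
                    if parent != UNKNOWN_PARENT and parent in pos:
                        p = pos[parent]
                        if state[p] == 1:
                            raise ValidationError(
                                f"pedigree cycle involving id "
                                f"{self.ids[p]!r}")
                        if state[p] == 0:
                            stack.append((p, False))
        return np.asarray(order, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.ids)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire and dam row indices into ``ids`` (-1 for unknown)."""
        pos = {i: k for k, i in enumerate(self.ids)}
        sire_ix = np.array([pos.get(s, -1) for s in self.sires], dtype=np.int64)
        dam_ix = np.array([pos.get(d, -1) for d in self.dams], dtype=np.int64)
        return sire_ix, dam_ix


@dataclass
class TraitTable:
    """Per-individual pseudo-phenotypes for one trait.

    Before :func:`deregress` only ``pta`` and ``reliability`` are set; the
    de-regressed record (``depta``) and its Garrick record weight
    (``record_weight``) are filled in afterwards.  ``h2`` is the trait
    heritability, constant within the table.
    """

    ids: list
    pta: np.ndarray
    reliability: np.ndarray
    h2: float
    depta: np.ndarray | None = None
    record_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pta = np.asarray(self.pta, dtype=np.float64)
        self.reliability = np.asarray(self.reliability, dtype=np.float64)
        if not (0.0 < self.h2 < 1.0):
            raise ValidationError(f"heritability {self.h2} outside (0,1)")
        if np.any(self.reliability <= 0.0) or np.any(self.reliability >= 1.0):
            raise ValidationError("reliability outside (0,1)")
        if len(self.ids) != len(self.pta) or len(self.ids) != len(self.reliability):
            raise ValidationError("trait table columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class QTLAnnotation:
    """Reported QTL intervals, 0-based half-open per chromosome."""

    chromosome: np.ndarray
    start_bp: np.ndarray
    stop_bp: np.ndarray

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.start_bp = np.asarray(self.start_bp, dtype=np.int64)
        self.stop_bp = np.asarray(self.stop_bp, dtype=np.int64)
        if np.any(self.start_bp >= self.stop_bp):
            raise ValidationError("annotation interval with start >= stop")
        if np.any((self.chromosome < 1) | (self.chromosome > 29)):
            raise ValidationError("annotation chromosome outside 1-29")

    def __len__(self) -> int:
        return len(self.chromosome)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def read_pedigree(path) -> Pedigree:
    df = _read_tsv(path, ["id", "sire", "dam"])
    df = df.fillna(UNKNOWN_PARENT)
    return Pedigree(df["id"].to_numpy(object), df["sire"].to_numpy(object),
                    df["dam"].to_numpy(object))


def write_pedigree(ped: Pedigree, path) -> None:
    pd.DataFrame({"id": ped.ids, "sire": ped.sires, "dam": ped.dams}).to_csv(
        path, sep="\t", index=False)


def _parse_chrom(token: str):
    token = str(token)
    if token in ("unmapped", "sex"):
        return token
    try:
        return int(token)
    except ValueError as exc:
        raise ParseError(f"unrecognized chromosome label {token!r}") from exc


def read_marker_map(path) -> MarkerMap:
    df = _read_tsv(path, ["marker", "chrom", "pos"])
    chrom = np.array([_parse_chrom(c) for c in df["chrom"]], dtype=object)
    try:
        pos = df["pos"].astype(np.int64).to_numpy() - 1  # 1-based on disk
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer position ({exc})") from exc
    return MarkerMap(df["marker"].to_numpy(object), chrom, pos)


def write_marker_map(mm: MarkerMap, path) -> None:
    pd.DataFrame({"marker": mm.marker_id, "chrom": mm.chromosome,
                  "pos": mm.position_bp + 1}).to_csv(path, sep="\t",
                                                     index=False)


def read_genotypes(path, map_path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix (rows = individuals, columns = markers).

    ``dialect`` is ``"tsv"`` (first column ``id``, marker columns named by
    marker id) or ``"plink-raw"`` (PLINK ``.raw`` additive coding: the six
    leading FID/IID/PAT/MAT/SEX/PHENOTYPE columns are skipped and IID is
    the individual id).
    """
    mm = read_marker_map(map_path)
    if dialect == "tsv":
        df = _read_tsv(path, ["id"])
        ids = df["id"].tolist()
        body = df.drop(columns=["id"])
    elif dialect == "plink-raw":
        try:
            df = pd.read_csv(path, sep=r"\s+", dtype=str)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if not set(lead).issubset(df.columns):
            raise ParseError(f"{path}: not a PLINK .raw file")
        ids = df["IID"].tolist()
        body = df.drop(columns=lead)
        # .raw appends _<allele> to marker names
        body.columns = [c.rsplit("_", 1)[0] for c in body.columns]
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    want = list(mm.marker_id)
    missing_cols = [m for m in want if m not in body.columns]
    if missing_cols:
        raise ParseError(f"{path}: markers missing from matrix: "
                         f"{missing_cols[:5]}")
    body = body[want]
    calls = np.full(body.shape, np.nan)
    for j, col in enumerate(body.columns):
        raw = body[col].to_numpy()
        for i, tok in enumerate(raw):
            if tok in (None, "", "NA", "nan") or (isinstance(tok, float)
                                                  and np.isnan(tok)):
                continue
            try:
                v = float(tok)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: bad genotype {tok!r} (individual line {i + 2}, "
                    f"marker {col})") from exc
            calls[i, j] = v
    try:
        return GenotypeMatrix(ids, calls, mm)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_genotypes(g: GenotypeMatrix, path, map_path=None) -> None:
    body = pd.DataFrame(g.calls, columns=list(g.map.marker_id))
    # integers on disk, empty cell for missing
    body = body.map(lambda v: "" if np.isnan(v) else str(int(v)))
    body.insert(0, "id", g.individual_ids)
    body.to_csv(path, sep="\t", index=False)
    if map_path is not None:
        write_marker_map(g.map, map_path)


def read_traits(path, h2: float) -> TraitTable:
    df = _read_tsv(path, ["id", "pta", "reliability"])
    try:
        pta = df["pta"].astype(float).to_numpy()
        rel = df["reliability"].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric trait value ({exc})") from exc
    return TraitTable(df["id"].tolist(), pta, rel, h2)


def write_traits(t: TraitTable, path) -> None:
    out = {"id": t.ids, "pta": t.pta, "reliability": t.reliability}
    if t.depta is not None:
        out["depta"] = t.depta
        out["record_weight"] = t.record_weight
    pd.DataFrame(out).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_annotation(path) -> QTLAnnotation:
    """BED-like TSV with columns chrom, start, stop (1-based inclusive)."""
    df = _read_tsv(path, ["chrom", "start", "stop"])
    try:
        chrom = df["chrom"].astype(np.int64).to_numpy()
        start = df["start"].astype(np.int64).to_numpy() - 1
        stop = df["stop"].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer annotation field ({exc})") from exc
    return QTLAnnotation(chrom, start, stop)


def write_annotation(a: QTLAnnotation, path) -> None:
    pd.DataFrame({"chrom": a.chromosome, "start": a.start_bp + 1,
                  "stop": a.stop_bp}).to_csv(path, sep="\t", index=False)


def read_tables(pedigree_path, genotype_path, map_path, trait_path, h2,
                annotation_path=None, genotype_dialect="tsv"):
    """Load all inputs; returns (Pedigree, GenotypeMatrix, TraitTable,
    QTLAnnotation-or-None)."""
    ped = read_pedigree(pedigree_path)
    g = read_genotypes(genotype_path, map_path, dialect=genotype_dialect)
    t = read_traits(trait_path, h2)
    ann = read_annotation(annotation_path) if annotation_path else None
    return ped, g, t, ann


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def orient_to_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip counted alleles so every counted-allele frequency is <= 0.5."""
    p = g.allele_freq()
    flip = p > 0.5
    calls = g.calls.copy()
    calls[:, flip] = 2.0 - calls[:, flip]
    return replace(g, calls=calls)


def qc_filter_markers(g: GenotypeMatrix, maf_min: float = 0.05,
                      callrate_min: float = 0.99):
    """Drop markers with MAF < maf_min, call rate < callrate_min, or a
    non-autosomal map entry.  Returns (filtered matrix, report DataFrame).

    Both thresholds are strict: a marker sitting exactly at the boundary is
    retained.  MAF is computed as min(p, 1-p) of the counted-allele
    frequency on the current cohort.
    """
    p = g.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    callrate = 1.0 - np.isnan(g.calls).mean(axis=0)
    autosomal = g.map.is_autosomal()

    reasons = []
    keep = np.ones(g.n_markers, dtype=bool)
    for j in range(g.n_markers):
        why = []
        if not autosomal[j]:
            why.append("non_autosomal")
        if maf[j] < maf_min or np.isnan(maf[j]):
            why.append("low_maf")
        if callrate[j] < callrate_min:
            why.append("low_callrate")
        if why:
            keep[j] = False
            reasons.append((g.map.marker_id[j], ";".join(why)))
    if not keep.any():
        raise ValidationError("QC removed every marker (empty panel)")
    report = pd.DataFrame(reasons, columns=["marker", "reason"])
    out = GenotypeMatrix(g.individual_ids, g.calls[:, keep],
                         g.map.subset(keep))
    return out, report


def qc_filter_individuals(g: GenotypeMatrix, callrate_min: float = 0.99):
    """Drop individuals with genotype call rate < callrate_min (strict)."""
    callrate = 1.0 - np.isnan(g.calls).mean(axis=1)
    keep = callrate >= callrate_min
    if not keep.any():
        raise ValidationError("QC removed every individual (empty cohort)")
    report = pd.DataFrame(
        {"id": [g.individual_ids[i] for i in np.flatnonzero(~keep)],
         "callrate": callrate[~keep]})
    out = GenotypeMatrix([g.individual_ids[i] for i in np.flatnonzero(keep)],
                         g.calls[keep], g.map)
    return out, report


def impute_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Fill each missing call with the marker's most frequent observed
    genotype (ties broken toward the smaller genotype).

    A naive single-site imputer: no linkage information is used.  The
    ``imputed`` flag array records which calls were filled.
    """
    calls = g.calls.copy()
    imputed = np.zeros_like(calls, dtype=bool)
    for j in range(g.n_markers):
        col = calls[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        if miss.all():
            raise ValidationError(
                f"marker {g.map.marker_id[j]!r} entirely missing")
        counts = [(col[~miss] == v).sum() for v in (0.0, 1.0, 2.0)]
        mode = float(np.argmax(counts))  # argmax -> smallest genotype on tie
        col[miss] = mode
        imputed[:, j] = miss
    return replace(g, calls=calls, imputed=imputed)


# ---------------------------------------------------------------------------
# de-regression
# ---------------------------------------------------------------------------


def garrick_weight(reliability, h2, c_constant=0.5):
    """Garrick-style record weight w = (1-h2) / ((c + (1-r2)/r2) * h2)."""
    r2 = np.asarray(reliability, dtype=float)
    w = (1.0 - h2) / ((c_constant + (1.0 - r2) / r2) * h2)
    return w


def deregress(t: TraitTable, c_constant: float = 0.5,
              rel_min: float = 0.2) -> TraitTable:
    """De-regress PTA into pseudo-phenotypes and attach record weights.

    dePTA = PTA / r2 (single-record form; no parent-average removal) and
    the record weight is :func:`garrick_weight`.  Records whose reliability
    is <= ``rel_min`` are dropped (strict "higher than" filter).  Under the
    single-record form the de-regressed record is a rescaling of the PTA,
    so its reliability equals the PTA reliability and the filter can be
    applied to either.
    """
    r2 = t.reliability
    if np.any(r2 <= 0.0):
        raise ValidationError("reliability of 0 cannot be de-regressed")
    keep = r2 > rel_min
    if not keep.any():
        raise ValidationError("reliability filter removed every record")
    depta = t.pta[keep] / r2[keep]
    w = garrick_weight(r2[keep], t.h2, c_constant)
    if not np.all(np.isfinite(w)) or np.any(w <= 0.0):
        raise ValidationError("non-finite or non-positive record weight")
    return TraitTable([t.ids[i] for i in np.flatnonzero(keep)],
                      t.pta[keep], r2[keep], t.h2, depta=depta,
                      record_weight=w)
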
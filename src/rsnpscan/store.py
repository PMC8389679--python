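"""Embedded relational store for pipeline results.

Four tables mirror the pipeline's outputs: ``snp_info`` (the SNPs),
``gene_info`` (the genes), ``snp_region`` (SNP-to-promoter links with the
signed TSS distance) and ``tfbs_results`` (per-site consequence records).
``snp_region`` keys must exist in ``snp_info`` and ``gene_info``, and
``tfbs_results`` keys in ``snp_region``; violations roll the whole write
back.  A single SQLite file replaces a server database — same logical
schema, zero deployment.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .consequences import RSNP_CONSEQUENCES, ConsequenceRecord
from .genomic import SnpRecord
from .promoters import SnpRegionRow

TABLES = ("snp_info", "gene_info", "snp_region", "tfbs_results")

_SCHEMA = """
CREATE TABLE IF NOT EXISTS snp_info (
    snp_id TEXT NOT NULL,
    chrom  TEXT NOT NULL,
    pos    INTEGER NOT NULL,
    ref    TEXT NOT NULL,
    alt    TEXT NOT NULL,
    UNIQUE (snp_id, alt)
);
CREATE TABLE IF NOT EXISTS gene_info (
    gene_id   TEXT PRIMARY KEY,
    gene_name TEXT,
    chrom     TEXT NOT NULL,
    start     INTEGER,
    end       INTEGER,
    strand    TEXT
);
CREATE TABLE IF NOT EXISTS snp_region (
    snp_id        TEXT NOT NULL,
    gene_id       TEXT NOT NULL,
    transcript_id TEXT NOT NULL,
    dist_tss      INTEGER NOT NULL,
    UNIQUE (snp_id, gene_id, transcript_id)
);
CREATE TABLE IF NOT EXISTS tfbs_results (
    snp_id          TEXT NOT NULL,
    pwm_id          TEXT NOT NULL,
    strand          TEXT NOT NULL,
    start           INTEGER NOT NULL,
    allele_presence TEXT NOT NULL,
    ref_mss REAL, ref_css REAL, alt_mss REAL, alt_css REAL,
    consequence     TEXT NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_snp_info_pos ON snp_info (chrom, pos);
CREATE INDEX IF NOT EXISTS idx_region_snp ON snp_region (snp_id);
CREATE INDEX IF NOT EXISTS idx_region_gene ON snp_region (gene_id);
CREATE INDEX IF NOT EXISTS idx_tfbs_snp ON tfbs_results (snp_id);
"""


@dataclass(frozen=True)
class GeneInfo:
    """One row of the gene table."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int | None
    end: int | None
    strand: str


class IntegrityError(Exception):
    """Referential-integrity violation; the write was rolled back."""


class ResultStore:
    """Open (creating if needed) the single-file result database."""

    def __init__(self, path: str | Path = ":memory:") -> None:
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "ResultStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- writing ----------------------------------------------------------

    def write_results(self,
                      snps: list[SnpRecord],
                      genes: list[GeneInfo],
                      regions: list[SnpRegionRow],
                      tfbs: list[ConsequenceRecord]) -> dict[str, int]:
        """Insert all four tables atomically; returns per-table row counts.

        Referential integrity is checked against the union of existing and
        incoming keys; any violation rolls back the entire write.
        """
        known_snps = {r[0] for r in self.conn.execute(
            "SELECT snp_id FROM snp_info")} | {s.snp_id for s in snps}
        known_genes = {r[0] for r in self.conn.execute(
            "SELECT gene_id FROM gene_info")} | {g.gene_id for g in genes}
        region_snps = {r[0] for r in self.conn.execute(
            "SELECT snp_id FROM snp_region")} | {r.snp_id for r in regions}
        for r in regions:
            if r.snp_id not in known_snps:
                raise IntegrityError(f"snp_region.snp_id {r.snp_id!r} not in snp_info")
            if r.gene_id not in known_genes:
                raise IntegrityError(f"snp_region.gene_id {r.gene_id!r} not in gene_info")
        for t in tfbs:
            if t.snp_id not in region_snps:
                raise IntegrityError(f"tfbs_results.snp_id {t.snp_id!r} not in snp_region")
        try:
            with self.conn:  # one transaction
                self.conn.executemany(
                    "INSERT INTO snp_info VALUES (?,?,?,?,?)",
                    [(s.snp_id, s.chrom, s.pos, s.ref, s.alt) for s in snps])
                self.conn.executemany(
                    "INSERT INTO gene_info VALUES (?,?,?,?,?,?)",
                    [(g.gene_id, g.gene_name, g.chrom, g.start, g.end, g.strand)
                     for g in genes])
                self.conn.executemany(
                    "INSERT INTO snp_region VALUES (?,?,?,?)",
                    [(r.snp_id, r.gene_id, r.transcript_id, r.dist_tss)
                     for r in regions])
                self.conn.executemany(
                    "INSERT INTO tfbs_results VALUES (?,?,?,?,?,?,?,?,?,?)",
                    [(t.snp_id, t.pwm_id, t.strand, t.start, t.allele_presence,
                      t.ref_mss, t.ref_css, t.alt_mss, t.alt_css, t.consequence)
                     for t in tfbs])
        except sqlite3.IntegrityError as exc:
            raise IntegrityError(str(exc)) from exc
        return {"snp_info": len(snps), "gene_info": len(genes),
                "snp_region": len(regions), "tfbs_results": len(tfbs)}

    # -- reading ----------------------------------------------------------

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLES:
            raise ValueError(f"unknown table {name!r}")
        return pd.read_sql_query(f"SELECT * FROM {name}", self.conn)

    def counts(self) -> dict[str, int]:
        return {t: self.conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0]
                for t in TABLES}

    def _snp_ids_for(self, by: str, key) -> list[str]:
        cur = self.conn
        if by == "rsid":
            rows = cur.execute("SELECT DISTINCT snp_id FROM snp_info WHERE snp_id=?",
                               (str(key),))
        elif by == "position":
            if isinstance(key, str):
                m = re.fullmatch(r"([^:]+):(\d+)", key.strip())
                if not m:
                    raise ValueError(f"malformed position {key!r}; want chrom:pos")
                key = (m.group(1), int(m.group(2)))
            chrom, pos = key
            rows = cur.execute(
                "SELECT DISTINCT snp_id FROM snp_info WHERE chrom=? AND pos=?",
                (chrom, int(pos)))
        elif by == "region":
            if isinstance(key, str):
                m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", key.strip())
                if not m:
                    raise ValueError(
                        f"malformed region {key!r}; want chrom:start-end")
                key = (m.group(1), int(m.group(2)), int(m.group(3)))
            chrom, start, end = key
            if start > end:
                raise ValueError(f"region start {start} > end {end}")
            rows = cur.execute(
                "SELECT DISTINCT snp_id FROM snp_info "
                "WHERE chrom=? AND pos BETWEEN ? AND ?", (chrom, start, end))
        elif by == "gene":
            rows = cur.execute(
                "SELECT DISTINCT r.snp_id FROM snp_region r "
                "JOIN gene_info g ON g.gene_id = r.gene_id "
                "WHERE g.gene_id=? OR g.gene_name=?", (str(key), str(key)))
        else:
            raise ValueError(f"unknown query mode {by!r}")
        return [r[0] for r in rows]

    def query(self, by: str, key,
              promoter_filter: tuple[int, int] | None = None,
              ) -> dict[str, pd.DataFrame]:
        """Search by rsid, position ('chrom:pos'), region ('chrom:start-end')
        or gene (id or name); returns the four joined table slices.

        ``promoter_filter=(up_bp, down_bp)`` keeps snp_region rows with
        ``-up_bp <= dist_tss <= down_bp`` (the user-narrowed promoter) and
        restricts the other tables to the surviving SNPs.
        """
        snp_ids = self._snp_ids_for(by, key)
        if not snp_ids:
            return {t: self.table(t).iloc[0:0] for t in TABLES}
        ph = ",".join("?" * len(snp_ids))
        region = pd.read_sql_query(
            f"SELECT * FROM snp_region WHERE snp_id IN ({ph})",
            self.conn, params=snp_ids)
        if promoter_filter is not None:
            up_bp, down_bp = promoter_filter
            region = region[(region.dist_tss >= -up_bp)
                            & (region.dist_tss <= down_bp)].reset_index(drop=True)
        kept = sorted(set(region.snp_id)) if by == "gene" or promoter_filter \
            else snp_ids
        if not kept:
            return {"snp_info": self.table("snp_info").iloc[0:0],
                    "gene_info": self.table("gene_info").iloc[0:0],
                    "snp_region": region,
                    "tfbs_results": self.table("tfbs_results").iloc[0:0]}
        ph2 = ",".join("?" * len(kept))
        snp_info = pd.read_sql_query(
            f"SELECT * FROM snp_info WHERE snp_id IN ({ph2})",
            self.conn, params=kept)
        gene_ids = sorted(set(region.gene_id))
        if gene_ids:
            phg = ",".join("?" * len(gene_ids))
            gene_info = pd.read_sql_query(
                f"SELECT * FROM gene_info WHERE gene_id IN ({phg})",
                self.conn, params=gene_ids)
        else:
            gene_info = self.table("gene_info").iloc[0:0]
        tfbs = pd.read_sql_query(
            f"SELECT * FROM tfbs_results WHERE snp_id IN ({ph2})",
            self.conn, params=kept)
        return {"snp_info": snp_info, "gene_info": gene_info,
                "snp_region": region, "tfbs_results": tfbs}

    def rsnp_ids(self) -> set[str]:
        """SNP ids with at least one loss/gain/score-change site."""
        ph = ",".join("?" * len(RSNP_CONSEQUENCES))
        rows = self.conn.execute(
            f"SELECT DISTINCT snp_id FROM tfbs_results WHERE consequence IN ({ph})",
            sorted(RSNP_CONSEQUENCES))
        return {r[0] for r in rows}

    # -- CSV export / import ----------------------------------------------

    def export_csv(self, out_dir: str | Path, per_chromosome: bool = False) -> list[Path]:
        """Write each table as an RFC-4180 CSV with a header row.

        ``per_chromosome=True`` additionally splits the chromosome-keyed
        tables into one file per chromosome.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for name in TABLES:
            df = self.table(name)
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
            if per_chromosome and "chrom" in df.columns:
                for chrom, part in df.groupby("chrom"):
                    p = out_dir / f"{name}.{chrom}.csv"
                    part.to_csv(p, index=False)
                    written.append(p)
        return written

    @classmethod
    def import_csv(cls, in_dir: str | Path,
                   path: str | Path = ":memory:") -> "ResultStore":
        """Rebuild a store from an :meth:`export_csv` directory."""
        in_dir = Path(in_dir)
        store = cls(path)
        with store.conn:
            for name in TABLES:
                df = pd.read_csv(in_dir / f"{name}.csv")
                df.to_sql(name, store.conn, if_exists="append", index=False)
        return store
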
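"""Structural validators for the emitted genome-browser formats.

Self-contained: these check the written *text* against the format contracts
(BED12 block bookkeeping, GCT dims line, track-hub reference chain) without
using the writer code.
"""

from __future__ import annotations

from pathlib import Path


def validate_bed12_line(line: str) -> list[str]:
    """Return a list of problems with one BED12 line (empty if valid)."""
    problems: list[str] = []
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 12:
        return [f"expected 12 columns, got {len(fields)}"]
    (chrom, start_s, end_s, name, score_s, strand,
     thick_start_s, thick_end_s, rgb, count_s, sizes_s, starts_s) = fields
    try:
        start, end = int(start_s), int(end_s)
        thick_start, thick_end = int(thick_start_s), int(thick_end_s)
        score = int(score_s)
        count = int(count_s)
        sizes = [int(x) for x in sizes_s.rstrip(",").split(",")]
        starts = [int(x) for x in starts_s.rstrip(",").split(",")]
        rgb_parts = [int(x) for x in rgb.split(",")]
    except ValueError:
        return ["non-numeric field"]
    if not chrom or not name:
        problems.append("empty chrom or name")
    if strand not in ("+", "-"):
        problems.append(f"bad strand {strand!r}")
    if not 0 <= score <= 1000:
        problems.append(f"score {score} outside 0-1000")
    if not start <= thick_start <= thick_end <= end:
        problems.append("thick region outside chromStart..chromEnd")
    if len(rgb_parts) != 3 or any(not 0 <= c <= 255 for c in rgb_parts):
        problems.append(f"bad itemRgb {rgb!r}")
    if len(sizes) != count or len(starts) != count:
        problems.append("blockSizes/blockStarts count != blockCount")
        return problems
    if starts[0] != 0:
        problems.append("first blockStart != 0")
    if starts[-1] + sizes[-1] != end - start:
        problems.append("last block does not end at chromEnd")
    for (s1, z1), s2 in zip(zip(starts, sizes), starts[1:]):
        if s1 + z1 > s2:
            problems.append("blocks overlap or are out of order")
            break
    return problems


def validate_bed_file(path: Path) -> list[str]:
    problems = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        for problem in validate_bed12_line(line):
            problems.append(f"{path.name}:{lineno}: {problem}")
    return problems


def bed_names(path: Path) -> set[str]:
    return {line.split("\t")[3] for line in path.read_text().splitlines() if line.strip()}


def validate_gct_file(path: Path) -> list[str]:
    lines = path.read_text().splitlines()
    problems = []
    if not lines or lines[0] != "#1.2":
        return [f"{path.name}: missing #1.2 version line"]
    try:
        n_rows, n_cols = (int(x) for x in lines[1].split("\t"))
    except (IndexError, ValueError):
        return [f"{path.name}: bad dims line"]
    header = lines[2].split("\t")
    if header[:2] != ["Name", "Description"] or len(header) != 2 + n_cols:
        problems.append(f"{path.name}: header does not match {n_cols} sample columns")
    body = lines[3:]
    if len(body) != n_rows:
        problems.append(f"{path.name}: dims say {n_rows} rows, file has {len(body)}")
    for lineno, line in enumerate(body, start=4):
        if len(line.split("\t")) != 2 + n_cols:
            problems.append(f"{path.name}:{lineno}: wrong column count")
    names = [line.split("\t")[0] for line in body]
    if len(names) != len(set(names)):
        problems.append(f"{path.name}: duplicate row names")
    return problems


def validate_track_hub(hub_dir: Path) -> list[str]:
    """Follow the hub.txt -> genomes.txt -> trackDb.txt reference chain."""
    problems = []
    hub_txt = hub_dir / "hub.txt"
    if not hub_txt.exists():
        return ["hub.txt missing"]
    hub_fields = dict(
        line.split(" ", 1) for line in hub_txt.read_text().splitlines() if " " in line
    )
    genomes_name = hub_fields.get("genomesFile")
    if not genomes_name or not (hub_dir / genomes_name).exists():
        return [f"genomesFile {genomes_name!r} unresolvable"]
    if "email" not in hub_fields:
        problems.append("hub.txt missing email")
    genome_fields = dict(
        line.split(" ", 1)
        for line in (hub_dir / genomes_name).read_text().splitlines()
        if " " in line
    )
    trackdb_rel = genome_fields.get("trackDb")
    if not trackdb_rel or not (hub_dir / trackdb_rel).exists():
        return [f"trackDb {trackdb_rel!r} unresolvable"]
    trackdb = (hub_dir / trackdb_rel).read_text()
    if "track " not in trackdb:
        problems.append("trackDb.txt has no track stanzas")
    return problems
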
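"""Line-numbered validation of the pipeline's text formats."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

SCHEMAS = ("bin_counts_tsv", "seg_tsv", "features_csv", "patients_csv", "grades_csv")


@dataclass
class ValidationReport:
    schema: str
    path: str
    violations: list = field(default_factory=list)  # (line_number, message)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, line: int, message: str) -> None:
        self.violations.append((line, message))


def _split(line: str, sep: str) -> list[str]:
    return line.rstrip("\n").split(sep)


def _check_header(report, header, expected, sep_name):
    if header != expected:
        report.add(1, f"header must be {expected} ({sep_name}-separated), got {header}")
        return False
    return True


def _float(report, line_no, name, value):
    try:
        return float(value)
    except ValueError:
        report.add(line_no, f"{name} must be numeric, got {value!r}")
        return None


def _validate_bin_counts(lines, report):
    expected = ["chrom", "start", "end", "gc", "count"]
    if not _check_header(report, _split(lines[0], "\t"), expected, "tab"):
        return
    prev = {}
    for ln, line in enumerate(lines[1:], start=2):
        parts = _split(line, "\t")
        if len(parts) != 5:
            report.add(ln, f"expected 5 tab-separated fields, got {len(parts)}")
            continue
        chrom, start, end, gc, count = parts
        s = _float(report, ln, "start", start)
        e = _float(report, ln, "end", end)
        g = _float(report, ln, "gc", gc)
        c = _float(report, ln, "count", count)
        if None in (s, e, g, c):
            continue
        if e <= s:
            report.add(ln, "end must exceed start")
        if not 0 <= g <= 1:
            report.add(ln, "gc must be in [0, 1]")
        if c < 0 or c != int(c):
            report.add(ln, "count must be a non-negative integer")
        if chrom in prev and s < prev[chrom]:
            report.add(ln, f"bins on {chrom} out of order")
        prev[chrom] = e


def _validate_seg(lines, report):
    expected = ["sample", "chrom", "start", "end", "n_bins", "mean_cn", "mosaic_est", "direction"]
    if not _check_header(report, _split(lines[0], "\t"), expected, "tab"):
        return
    for ln, line in enumerate(lines[1:], start=2):
        parts = _split(line, "\t")
        if len(parts) != 8:
            report.add(ln, f"expected 8 tab-separated fields, got {len(parts)} (truncated line?)")
            continue
        _, _, start, end, n_bins, mean_cn, mosaic, direction = parts
        s = _float(report, ln, "start", start)
        e = _float(report, ln, "end", end)
        nb = _float(report, ln, "n_bins", n_bins)
        mc = _float(report, ln, "mean_cn", mean_cn)
        mo = _float(report, ln, "mosaic_est", mosaic)
        if None in (s, e, nb, mc, mo):
            continue
        if e <= s:
            report.add(ln, "end must exceed start")
        if nb < 1:
            report.add(ln, "n_bins must be >= 1")
        if mc < 0:
            report.add(ln, "mean_cn must be non-negative")
        if not 0 <= mo <= 1:
            report.add(ln, "mosaic_est must be in [0, 1]")
        if direction not in ("gain", "loss", "neutral"):
            report.add(ln, f"direction must be gain/loss/neutral, got {direction!r}")


def _validate_features(lines, report):
    from nics.feature_extraction import FEATURE_NAMES

    expected = ["embryo_id", *FEATURE_NAMES]
    if not _check_header(report, _split(lines[0], ","), expected, "comma"):
        return
    for ln, line in enumerate(lines[1:], start=2):
        parts = _split(line, ",")
        if len(parts) != len(expected):
            report.add(ln, f"expected {len(expected)} fields, got {len(parts)}")
            continue
        vals = [_float(report, ln, name, v) for name, v in zip(expected[1:], parts[1:])]
        if None in vals:
            continue
        for k in range(6):  # ordinal call features
            if vals[k] not in (0, 1, 2):
                report.add(ln, f"{expected[1 + k]} must be 0/1/2")
        if not 0 <= vals[6] <= 3:
            report.add(ln, "f7_euploid_resolution_count must be in 0..3")
        if not 0 <= vals[7] <= 24:
            report.add(ln, "f8_abnormal_chrom_count must be in 0..24")
        if not 0 <= vals[8] <= 1:
            report.add(ln, "f9_max_mosaic_fraction must be in [0, 1]")
        if vals[9] < 0:
            report.add(ln, "f10 must be >= 0")
        if vals[10] not in (0, 1):
            report.add(ln, "f11_sex_chrom_abnormal must be 0/1")


def _validate_patients(lines, report):
    from nics.clinical_outcomes import OUTCOME_COLUMNS, PATIENT_COLUMNS

    header = _split(lines[0], ",")
    missing = [c for c in PATIENT_COLUMNS if c not in header]
    if missing:
        report.add(1, f"missing columns {missing}")
        return
    pos = {c: header.index(c) for c in header}
    for ln, line in enumerate(lines[1:], start=2):
        parts = _split(line, ",")
        if len(parts) != len(header):
            report.add(ln, f"expected {len(header)} fields, got {len(parts)}")
            continue
        outcomes = {}
        for col in OUTCOME_COLUMNS:
            v = _float(report, ln, col, parts[pos[col]])
            if v is None or v not in (0, 1):
                report.add(ln, f"{col} must be 0/1")
                v = None
            outcomes[col] = v
        b, c, o, l = (outcomes[k] for k in OUTCOME_COLUMNS)
        if None not in (b, c, o, l) and not (b >= c >= o >= l):
            report.add(
                ln,
                "outcome nesting violated: live_birth <= ongoing <= clinical <= biochemical",
            )
        if parts[pos["group"]] not in ("NICS", "control"):
            report.add(ln, f"group must be NICS/control, got {parts[pos['group']]!r}")


def _validate_grades(lines, report):
    expected = ["embryo_id", "p_euploid", "grade", "transfer_rank"]
    if not _check_header(report, _split(lines[0], ","), expected, "comma"):
        return
    for ln, line in enumerate(lines[1:], start=2):
        parts = _split(line, ",")
        if len(parts) != 4:
            report.add(ln, f"expected 4 fields, got {len(parts)}")
            continue
        p = _float(report, ln, "p_euploid", parts[1])
        if p is not None and not 0 <= p <= 1:
            report.add(ln, "p_euploid must be in [0, 1]")
        if parts[2] not in ("A", "B", "C"):
            report.add(ln, f"grade must be A/B/C, got {parts[2]!r}")


_VALIDATORS = {
    "bin_counts_tsv": _validate_bin_counts,
    "seg_tsv": _validate_seg,
    "features_csv": _validate_features,
    "patients_csv": _validate_patients,
    "grades_csv": _validate_grades,
}


def validate_formats(path: str | Path, schema: str) -> ValidationReport:
    """Validate a file against a named schema; pass/fail with line numbers."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {SCHEMAS}")
    report = ValidationReport(schema=schema, path=str(path))
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        report.add(0, "empty file")
        return report
    _VALIDATORS[schema](lines, report)
    return report
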
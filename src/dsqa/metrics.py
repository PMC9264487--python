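"""Response-judgment metrics for end-to-end answer quality.

Human judges grade each system response on a 1-4 scale (1 incorrect,
2 incorrect but related, 3 correct but incomplete, 4 correct and complete).
Grades transfer to a 0-3 score scale for the average; success-at-grade and
the response error rate are count ratios:

    average score = mean(grade - 1)                     in [0, 3]
    succ@i+       = |{grade >= i}| / N,  i in {2,3,4}   in [0, 1]
    RER           = |{grade < 2}| / N = 1 - succ@2+     in [0, 1]

The RER definition here — the fraction of responses judged outright
incorrect — is this package's reading; it makes RER the exact complement of
succ@2+, which holds for the pairs of values this metric family is quoted
with in the consumer-health QA literature.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class JudgedResponse:
    qid: str
    grade: int

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4):
            raise ValueError(f"grade must be in 1..4, got {self.grade}")


def average_score(judgments: list[JudgedResponse]) -> float:
    """Mean judged score after the 1-4 -> 0-3 grade transfer."""
    if not judgments:
        raise ValueError("empty judgment list")
    return sum(j.grade - 1 for j in judgments) / len(judgments)


def succ_at(judgments: list[JudgedResponse], i: int) -> float:
    """Fraction of responses graded at least ``i`` (i in 2..4)."""
    if not judgments:
        raise ValueError("empty judgment list")
    if i not in (2, 3, 4):
        raise ValueError(f"i must be in 2..4, got {i}")
    return sum(j.grade >= i for j in judgments) / len(judgments)


def response_error_rate(judgments: list[JudgedResponse]) -> float:
    """Fraction of responses judged incorrect (grade 1); 1 - succ@2+."""
    if not judgments:
        raise ValueError("empty judgment list")
    return sum(j.grade < 2 for j in judgments) / len(judgments)


def judgment_report(judgments: list[JudgedResponse]) -> dict:
    """The full metric bundle as a JSON-ready dict."""
    return {
        "average_score": average_score(judgments),
        "succ@2plus": succ_at(judgments, 2),
        "succ@3plus": succ_at(judgments, 3),
        "succ@4plus": succ_at(judgments, 4),
        "rer": response_error_rate(judgments),
        "n": len(judgments),
    }


def read_judgments(path) -> list[JudgedResponse]:
    """Two-column delimited text: qid, grade (tab or whitespace separated)."""
    out: list[JudgedResponse] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'qid grade'")
            try:
                out.append(JudgedResponse(parts[0], int(parts[1])))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return out
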
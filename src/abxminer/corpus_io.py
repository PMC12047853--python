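"""Reading and writing post corpora as JSON-lines.

One JSON object per line with keys: id, source, timestamp (ISO-8601),
author, text.  A corpus in memory is a pandas DataFrame with those columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

POST_COLUMNS = ["id", "source", "timestamp", "author", "text"]


def posts_to_frame(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=POST_COLUMNS)
    if df["id"].duplicated().any():
        raise ValueError("post ids must be unique within a corpus")
    return df


def read_posts(path: str | Path) -> pd.DataFrame:
    records = [json.loads(line) for line in Path(path).read_text().splitlines()
               if line.strip()]
    return posts_to_frame(records)


def write_posts(posts: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in posts[POST_COLUMNS].to_dict("records"):
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
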
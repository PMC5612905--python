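"""Single-file embedded relational store.

The schema mirrors the notebook's central data-model split: a
``molecules`` table indexed over the structure key, and a ``samples``
table whose rows are physical instances pointing at one molecule.
Reactions, collections, grants and tracking codes live beside them.
All JSON-typed columns hold UTF-8 JSON text.
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path

_SCHEMA = """
CREATE TABLE IF NOT EXISTS molecules(
  id INTEGER PRIMARY KEY,
  key_kind TEXT NOT NULL,
  key_value TEXT NOT NULL UNIQUE,
  molfile TEXT NOT NULL,
  iupac_name TEXT DEFAULT '',
  user_named INTEGER NOT NULL DEFAULT 0,
  sum_formula TEXT DEFAULT '',
  average_mass REAL DEFAULT 0.0,
  exact_mass REAL DEFAULT 0.0,
  canonical_smiles TEXT DEFAULT '',
  inchi_string TEXT DEFAULT '',
  cas_numbers TEXT NOT NULL DEFAULT '[]',
  external_refs TEXT NOT NULL DEFAULT '{}'
);
CREATE TABLE IF NOT EXISTS samples(
  id INTEGER PRIMARY KEY,
  molecule_id INTEGER NOT NULL REFERENCES molecules(id),
  initials TEXT NOT NULL,
  seq INTEGER NOT NULL,
  batch_path TEXT NOT NULL DEFAULT '[]',
  label TEXT NOT NULL UNIQUE,
  short_label TEXT,
  molfile TEXT NOT NULL,
  purity REAL NOT NULL DEFAULT 1.0,
  density REAL,
  molarity REAL,
  selected_cas TEXT,
  parent_id INTEGER REFERENCES samples(id),
  description TEXT NOT NULL DEFAULT '',
  location TEXT NOT NULL DEFAULT '',
  external_label TEXT NOT NULL DEFAULT ''
);
CREATE TABLE IF NOT EXISTS counters(
  user TEXT NOT NULL, kind TEXT NOT NULL, value INTEGER NOT NULL,
  PRIMARY KEY(user, kind)
);
CREATE TABLE IF NOT EXISTS analyses(
  id INTEGER PRIMARY KEY,
  sample_id INTEGER NOT NULL REFERENCES samples(id),
  kind TEXT NOT NULL DEFAULT '',
  status TEXT NOT NULL DEFAULT 'unconfirmed',
  attachments TEXT NOT NULL DEFAULT '[]',
  uuid TEXT
);
CREATE TABLE IF NOT EXISTS reactions(
  id INTEGER PRIMARY KEY,
  label TEXT UNIQUE,
  name TEXT NOT NULL DEFAULT '',
  status TEXT NOT NULL DEFAULT 'planned',
  temperature TEXT,
  description TEXT NOT NULL DEFAULT '',
  tlc TEXT NOT NULL DEFAULT '',
  refs TEXT NOT NULL DEFAULT '[]',
  created_at TEXT,
  updated_at TEXT
);
CREATE TABLE IF NOT EXISTS participants(
  id INTEGER PRIMARY KEY,
  reaction_id INTEGER NOT NULL REFERENCES reactions(id),
  sample_id INTEGER REFERENCES samples(id),
  role TEXT NOT NULL,
  target TEXT,
  real TEXT,
  is_reference INTEGER NOT NULL DEFAULT 0,
  solvent_name TEXT,
  solvent_density REAL,
  solvent_mw REAL,
  position INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS collections(
  id INTEGER PRIMARY KEY,
  owner TEXT NOT NULL,
  name TEXT NOT NULL,
  parent_id INTEGER REFERENCES collections(id),
  is_snapshot INTEGER NOT NULL DEFAULT 0,
  is_synchronized INTEGER NOT NULL DEFAULT 0,
  origin_id INTEGER
);
CREATE TABLE IF NOT EXISTS collection_elements(
  collection_id INTEGER NOT NULL REFERENCES collections(id),
  kind TEXT NOT NULL,
  element_id INTEGER NOT NULL,
  PRIMARY KEY(collection_id, kind, element_id)
);
CREATE TABLE IF NOT EXISTS grants(
  id INTEGER PRIMARY KEY,
  collection_id INTEGER NOT NULL REFERENCES collections(id),
  grantee TEXT NOT NULL,
  permission TEXT NOT NULL,
  detail INTEGER NOT NULL DEFAULT 3,
  revoked INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS user_groups(
  name TEXT NOT NULL, member TEXT NOT NULL,
  PRIMARY KEY(name, member)
);
CREATE TABLE IF NOT EXISTS codes(
  uuid TEXT PRIMARY KEY,
  kind TEXT NOT NULL,
  element_id INTEGER NOT NULL,
  UNIQUE(kind, element_id)
);
"""


class Store:
    """Thin wrapper over a sqlite connection with the elnkit schema."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.row_factory = sqlite3.Row
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    @classmethod
    def open(cls, path: str | Path) -> "Store":
        return cls(path)

    def close(self) -> None:
        self.conn.close()

    # -- small helpers ------------------------------------------------------

    def execute(self, sql: str, params: tuple = ()) -> sqlite3.Cursor:
        cur = self.conn.execute(sql, params)
        self.conn.commit()
        return cur

    def query(self, sql: str, params: tuple = ()) -> list[sqlite3.Row]:
        return self.conn.execute(sql, params).fetchall()

    def one(self, sql: str, params: tuple = ()) -> sqlite3.Row | None:
        return self.conn.execute(sql, params).fetchone()

    def next_counter(self, user: str, kind: str) -> int:
        """Advance and return the per-user sequence for ``kind``.

        Counters count items ever created and are never reused after
        deletion, keeping provenance stable.
        """
        row = self.one(
            "SELECT value FROM counters WHERE user=? AND kind=?", (user, kind))
        value = (row["value"] if row else 0) + 1
        self.execute(
            "INSERT INTO counters(user, kind, value) VALUES(?,?,?) "
            "ON CONFLICT(user, kind) DO UPDATE SET value=?",
            (user, kind, value, value))
        return value


def dumps(obj) -> str:
    return json.dumps(obj, ensure_ascii=False, sort_keys=True)


def loads(text: str | None, default):
    if not text:
        return default
    return json.loads(text)
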
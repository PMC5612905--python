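"""Collections, sharing and synchronization.

A collection groups samples, reactions and molecules for one owner.
Two ways of giving others access exist: *sharing* creates a frozen
snapshot — the recipient sees a fixed element set (though the contained
elements themselves stay live and editable per permission) — while
*synchronizing* links the recipient to the live collection, so later
additions and changes are visible.

Permissions form a cumulative ladder (read < write < share < delete <
import_elements < take_ownership): any action allowed at a level is
allowed at every higher level.  Detail levels 0..3 restrict which
fields of an element a recipient sees; restricted fields are absent
from the view, not blanked.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import (NotFoundError, PermissionDeniedError,
                     SnapshotFrozenError, ValidationError)
from .store import Store

PERMISSION_LEVELS = ("read", "write", "share", "delete", "import_elements",
                     "take_ownership")
ELEMENT_KINDS = ("sample", "reaction", "molecule")
DETAIL_LEVELS = (0, 1, 2, 3)

#: fields visible at each detail level (cumulative)
DETAIL_FIELDS: dict[int, frozenset[str]] = {
    0: frozenset({"id", "label", "short_label", "molfile", "formula"}),
    1: frozenset({"purity", "density", "molarity", "selected_cas",
                  "description", "location", "external_label"}),
    2: frozenset({"analyses"}),
}


def _rank(level: str) -> int:
    try:
        return PERMISSION_LEVELS.index(level)
    except ValueError:
        raise ValidationError(f"unknown permission level {level!r}") from None


@dataclass(frozen=True)
class ShareGrant:
    grantee: str                 # user name or "group:<name>"
    permission_level: str = "read"
    detail_level: int = 3

    def __post_init__(self):
        _rank(self.permission_level)
        if self.detail_level not in DETAIL_LEVELS:
            raise ValidationError("detail level must be 0..3")


@dataclass
class Collection:
    id: int
    owner: str
    name: str
    parent_id: int | None = None
    is_shared_snapshot: bool = False
    is_synchronized: bool = False
    origin_id: int | None = None


def permitted(grant: ShareGrant, action: str) -> bool:
    """Cumulative ladder: allowed iff the action's rank does not exceed
    the grant's."""
    return _rank(action) <= _rank(grant.permission_level)


# ---------------------------------------------------------------------------
# collection lifecycle
# ---------------------------------------------------------------------------


def create_collection(owner: str, name: str, store: Store,
                      parent_id: int | None = None) -> Collection:
    if parent_id is not None:
        _walk_parents(store, parent_id)  # raises on unknown parent
    cur = store.execute(
        "INSERT INTO collections(owner, name, parent_id) VALUES(?,?,?)",
        (owner, name, parent_id))
    return get_collection(store, cur.lastrowid)


def get_collection(store: Store, collection_id: int) -> Collection:
    row = store.one("SELECT * FROM collections WHERE id=?", (collection_id,))
    if row is None:
        raise NotFoundError(f"no collection with id {collection_id}")
    return Collection(
        id=row["id"], owner=row["owner"], name=row["name"],
        parent_id=row["parent_id"],
        is_shared_snapshot=bool(row["is_snapshot"]),
        is_synchronized=bool(row["is_synchronized"]),
        origin_id=row["origin_id"])


def _walk_parents(store: Store, collection_id: int) -> list[int]:
    chain = []
    current: int | None = collection_id
    while current is not None:
        if current in chain:
            raise ValidationError("collection hierarchy would contain a cycle")
        chain.append(current)
        current = get_collection(store, current).parent_id
    return chain


def element_refs(store: Store, collection_id: int) -> set[tuple[str, int]]:
    return {(r["kind"], r["element_id"]) for r in store.query(
        "SELECT kind, element_id FROM collection_elements"
        " WHERE collection_id=?", (collection_id,))}


def add_elements(coll: Collection, kind: str, ids: list[int], store: Store,
                 actor: str | None = None) -> None:
    if kind not in ELEMENT_KINDS:
        raise ValidationError(f"element kind must be one of {ELEMENT_KINDS}")
    coll = get_collection(store, coll.id)
    if coll.is_shared_snapshot:
        raise SnapshotFrozenError(
            "shared snapshots are a fixed set; new elements cannot be added")
    if actor is not None:
        _require(store, coll, actor, "write")
    for eid in ids:
        store.execute(
            "INSERT OR IGNORE INTO collection_elements(collection_id, kind,"
            " element_id) VALUES(?,?,?)", (coll.id, kind, eid))


def move_elements(src: Collection, dst: Collection, kind: str,
                  ids: list[int], store: Store,
                  actor: str | None = None) -> None:
    """Move element references between collections; the underlying
    elements are untouched."""
    src = get_collection(store, src.id)
    dst = get_collection(store, dst.id)
    if dst.is_shared_snapshot or src.is_shared_snapshot:
        raise SnapshotFrozenError(
            "shared snapshots are a fixed set; elements cannot be moved "
            "in or out")
    if actor is not None:
        _require(store, src, actor, "write")
        _require(store, dst, actor, "write")
    have = element_refs(store, src.id)
    missing = [e for e in ids if (kind, e) not in have]
    if missing:
        raise NotFoundError(
            f"{kind} ids {missing} are not in collection {src.id}")
    for eid in ids:
        store.execute(
            "DELETE FROM collection_elements WHERE collection_id=? AND kind=?"
            " AND element_id=?", (src.id, kind, eid))
        store.execute(
            "INSERT OR IGNORE INTO collection_elements(collection_id, kind,"
            " element_id) VALUES(?,?,?)", (dst.id, kind, eid))


# ---------------------------------------------------------------------------
# grants, groups, sharing
# ---------------------------------------------------------------------------


def define_group(name: str, members: list[str], store: Store) -> None:
    """Groups are flat member sets; nesting is unsupported."""
    store.execute("DELETE FROM user_groups WHERE name=?", (name,))
    for member in members:
        store.execute("INSERT INTO user_groups(name, member) VALUES(?,?)",
                      (name, member))


def _grantee_matches(store: Store, grantee: str, user: str) -> bool:
    if grantee == user:
        return True
    if grantee.startswith("group:"):
        row = store.one("SELECT 1 FROM user_groups WHERE name=? AND member=?",
                        (grantee[6:], user))
        return row is not None
    return False


def user_grant(store: Store, coll: Collection,
               user: str) -> ShareGrant | None:
    """Best applicable grant; the owner implicitly holds the top level."""
    if coll.owner == user:
        return ShareGrant(user, "take_ownership", 3)
    best: ShareGrant | None = None
    for row in store.query(
            "SELECT * FROM grants WHERE collection_id=? AND revoked=0",
            (coll.id,)):
        if not _grantee_matches(store, row["grantee"], user):
            continue
        g = ShareGrant(row["grantee"], row["permission"], row["detail"])
        if best is None or _rank(g.permission_level) > _rank(best.permission_level):
            best = g
    return best


def _require(store: Store, coll: Collection, actor: str, action: str) -> None:
    grant = user_grant(store, coll, actor)
    if grant is None or not permitted(grant, action):
        raise PermissionDeniedError(
            f"{actor} lacks {action!r} on collection {coll.id}")


def _record_grant(store: Store, collection_id: int, grant: ShareGrant) -> None:
    store.execute(
        "INSERT INTO grants(collection_id, grantee, permission, detail)"
        " VALUES(?,?,?,?)",
        (collection_id, grant.grantee, grant.permission_level,
         grant.detail_level))


def _check_no_escalation(store: Store, coll: Collection, actor: str,
                         grant: ShareGrant) -> None:
    actor_grant = user_grant(store, coll, actor)
    if actor_grant is None or not permitted(actor_grant, "share"):
        raise PermissionDeniedError(
            f"{actor} lacks 'share' on collection {coll.id}")
    if _rank(grant.permission_level) > _rank(actor_grant.permission_level):
        raise PermissionDeniedError(
            "cannot grant a higher permission level than one's own")


def share_snapshot(coll: Collection, grant: ShareGrant, store: Store,
                   actor: str | None = None) -> Collection | None:
    """Share a fixed set: copy the element refs into a new frozen
    collection owned by the sharer and grant the recipient access.

    Sharing a collection with oneself is a no-op (returns None).
    """
    coll = get_collection(store, coll.id)
    actor = actor or coll.owner
    _check_no_escalation(store, coll, actor, grant)
    if grant.grantee == coll.owner:
        return None
    cur = store.execute(
        "INSERT INTO collections(owner, name, is_snapshot, origin_id)"
        " VALUES(?,?,1,?)",
        (coll.owner, f"{coll.name} (shared)", coll.id))
    snap_id = cur.lastrowid
    for kind, eid in sorted(element_refs(store, coll.id)):
        store.execute(
            "INSERT INTO collection_elements(collection_id, kind, element_id)"
            " VALUES(?,?,?)", (snap_id, kind, eid))
    _record_grant(store, snap_id, grant)
    return get_collection(store, snap_id)


@dataclass(frozen=True)
class SyncLink:
    grant_id: int
    collection_id: int
    grantee: str


def sync_collection(coll: Collection, grant: ShareGrant, store: Store,
                    actor: str | None = None) -> SyncLink:
    """Synchronize: grant live access to the collection itself, so the
    recipient sees additions and changes made afterwards."""
    coll = get_collection(store, coll.id)
    actor = actor or coll.owner
    _check_no_escalation(store, coll, actor, grant)
    store.execute("UPDATE collections SET is_synchronized=1 WHERE id=?",
                  (coll.id,))
    _record_grant(store, coll.id, grant)
    row = store.one(
        "SELECT id FROM grants WHERE collection_id=? ORDER BY id DESC",
        (coll.id,))
    return SyncLink(grant_id=row["id"], collection_id=coll.id,
                    grantee=grant.grantee)


def revoke(link: SyncLink, store: Store) -> None:
    store.execute("UPDATE grants SET revoked=1 WHERE id=?", (link.grant_id,))


def visible_elements(store: Store, user: str,
                     collection_id: int) -> set[tuple[str, int]]:
    """Element refs the user can see in a collection, or raise."""
    coll = get_collection(store, collection_id)
    grant = user_grant(store, coll, user)
    if grant is None or not permitted(grant, "read"):
        raise PermissionDeniedError(
            f"{user} has no access to collection {collection_id}")
    return element_refs(store, collection_id)


# ---------------------------------------------------------------------------
# detail-level redaction
# ---------------------------------------------------------------------------


def redact_view(element: dict, detail_level: int) -> dict:
    """Project an element dict down to the fields of a detail level.

    Level 0 shows structure/formula/label only; 1 adds the properties
    tab; 2 adds analysis metadata; 3 is the identity view.  Composition
    at decreasing levels equals direct redaction at the lowest level.
    """
    if detail_level not in DETAIL_LEVELS:
        raise ValidationError("detail level must be 0..3")
    if detail_level == 3:
        return dict(element)
    allowed: set[str] = set()
    for level in range(detail_level + 1):
        allowed |= DETAIL_FIELDS.get(level, frozenset())
    return {k: v for k, v in element.items() if k in allowed}
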
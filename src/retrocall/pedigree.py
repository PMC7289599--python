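"""Pedigree container: animals, parent links and sequenced samples.

The pedigree drives the novelty logic of the insertion screen: de novo
calls require zero supporting reads in all sampled ancestors, and germline
calls require sharing between full siblings with parents clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

ANIMAL_COLUMNS = ["animal_id", "sire_id", "dam_id", "genotype", "strain"]
SAMPLE_COLUMNS = ["sample_id", "animal_id", "tissue", "age_class"]

#: sentinel for a missing parent in TSV files
MISSING_PARENT = "0"


@dataclass
class Pedigree:
    """Animals with sire/dam links plus the DNA samples drawn from them.

    ``animals`` columns: animal_id, sire_id, dam_id (None for founders),
    genotype, strain. ``samples`` columns: sample_id, animal_id, tissue,
    age_class. Parent links must be acyclic and every sample must map to a
    known animal.
    """

    animals: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ANIMAL_COLUMNS:
            if col not in self.animals.columns:
                raise ValueError(f"animals table missing column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"samples table missing column {col!r}")
        if self.animals["animal_id"].duplicated().any():
            raise ValueError("duplicate animal_id")
        known = set(self.animals["animal_id"])
        unknown = set(self.samples["animal_id"]) - known
        if unknown:
            raise ValueError(f"samples reference unknown animals: {sorted(unknown)}")
        self._parents = {
            row.animal_id: tuple(
                p if (p is not None and not pd.isna(p) and p != MISSING_PARENT) else None
                for p in (row.sire_id, row.dam_id)
            )
            for row in self.animals.itertuples()
        }
        for pa in self._parents.values():
            for p in pa:
                if p is not None and p not in known:
                    raise ValueError(f"unknown parent {p!r}")
        self._check_acyclic()
        self._animal_of_sample = dict(
            zip(self.samples["sample_id"], self.samples["animal_id"])
        )

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(a: str, stack: set) -> None:
            if a in stack:
                raise ValueError(f"pedigree cycle involving {a!r}")
            if state.get(a):
                return
            stack.add(a)
            for p in self._parents.get(a, (None, None)):
                if p is not None:
                    visit(p, stack)
            stack.discard(a)
            state[a] = 1

        for a in self._parents:
            visit(a, set())

    # ---------------------------------------------------------- relations
    def animal_ids(self) -> list[str]:
        return list(self.animals["animal_id"])

    def parents(self, animal: str) -> tuple:
        if animal not in self._parents:
            raise KeyError(f"animal {animal!r} not in pedigree")
        return self._parents[animal]

    def ancestors(self, animal: str) -> set:
        """Transitive parent closure over both lines (excludes the animal)."""
        out: set = set()
        frontier = [p for p in self.parents(animal) if p is not None]
        while frontier:
            a = frontier.pop()
            if a in out:
                continue
            out.add(a)
            frontier.extend(p for p in self._parents[a] if p is not None)
        return out

    def descendants(self, animal: str) -> set:
        children: dict[str, set] = {a: set() for a in self._parents}
        for a, (s, d) in self._parents.items():
            for p in (s, d):
                if p is not None:
                    children[p].add(a)
        out: set = set()
        frontier = list(children.get(animal, ()))
        while frontier:
            a = frontier.pop()
            if a in out:
                continue
            out.add(a)
            frontier.extend(children[a])
        return out

    def full_siblings(self, animal: str) -> set:
        """Animals with the same sire AND dam (excluding the animal itself);
        empty when either parent is unknown."""
        sire, dam = self.parents(animal)
        if sire is None or dam is None:
            return set()
        return {
            a
            for a, (s, d) in self._parents.items()
            if a != animal and s == sire and d == dam
        }

    def matings(self) -> dict[tuple, list]:
        """(sire, dam) -> offspring list, for animals with both parents known."""
        out: dict[tuple, list] = {}
        for a, (s, d) in self._parents.items():
            if s is not None and d is not None:
                out.setdefault((s, d), []).append(a)
        return out

    def samples_of(self, animal: str) -> list[str]:
        return list(
            self.samples.loc[self.samples["animal_id"] == animal, "sample_id"]
        )

    def animal_of(self, sample_id: str) -> str:
        try:
            return self._animal_of_sample[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in pedigree") from None

    def sampled_animals(self) -> set:
        return set(self.samples["animal_id"])

    # ---------------------------------------------------------------- I/O
    def to_tsv(self, animals_path, samples_path) -> None:
        a = self.animals.copy()
        a["sire_id"] = a["sire_id"].fillna(MISSING_PARENT)
        a["dam_id"] = a["dam_id"].fillna(MISSING_PARENT)
        a.to_csv(animals_path, sep="\t", index=False)
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, animals_path, samples_path) -> "Pedigree":
        a = pd.read_csv(animals_path, sep="\t", dtype=str)
        a.loc[a["sire_id"] == MISSING_PARENT, "sire_id"] = None
        a.loc[a["dam_id"] == MISSING_PARENT, "dam_id"] = None
        s = pd.read_csv(samples_path, sep="\t", dtype=str)
        return cls(a, s)
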
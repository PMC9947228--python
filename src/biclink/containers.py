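"""Core in-memory containers: genotype and lipidome matrices.

Genotype dosages use additive minor-allele coding (0/1/2) stored as a float
array with NaN marking missing calls.  Lipid concentrations are stored as a
participants x species :class:`pandas.DataFrame` of non-negative reals with a
class annotation per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: canonical lipid class labels used by the synthetic generator and readers
LIPID_CLASSES = ("sphingolipid", "glycerophospholipid", "glycerolipid", "sterol")


@dataclass
class SnpInfo:
    """Metadata for a single biallelic SNP (1-based physical position)."""

    id: str
    chromosome: str
    position: int
    allele_minor: str
    allele_major: str

    def __post_init__(self):
        if self.position < 1:
            raise ConfigurationError(f"SNP {self.id}: position must be >= 1")
        if self.allele_minor == self.allele_major:
            raise ConfigurationError(f"SNP {self.id}: alleles must differ")


@dataclass
class GenotypeMatrix:
    """Participants x SNPs dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_participants, n_snps)`` with entries in
        ``{0, 1, 2}`` or NaN for missing calls.
    participant_ids
        Unique participant identifiers, one per row.
    snps
        DataFrame with columns ``id, chromosome, position, allele_minor,
        allele_major`` aligned with the dosage columns.
    """

    dosages: np.ndarray
    participant_ids: list
    snps: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.participant_ids = list(self.participant_ids)
        n, m = self.dosages.shape
        if len(self.participant_ids) != n:
            raise ConfigurationError("participant_ids length != number of rows")
        if len(self.snps) != m:
            raise ConfigurationError("snps table length != number of columns")
        if len(set(self.participant_ids)) != n:
            raise ConfigurationError("duplicate participant identifiers")
        if self.snps["id"].duplicated().any():
            raise ConfigurationError("duplicate SNP identifiers")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ConfigurationError("dosages must be 0, 1, 2 or missing")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_participants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list:
        return self.snps["id"].tolist()

    def snp_index(self, snp_id: str) -> int:
        idx = self.snps.index[self.snps["id"] == snp_id]
        if len(idx) == 0:
            from .errors import LookupError_

            raise LookupError_(f"unknown SNP id: {snp_id}")
        return int(idx[0])

    def subset(self, participant_mask=None, snp_mask=None) -> "GenotypeMatrix":
        """Return a copy restricted to boolean masks over rows / columns."""
        pm = np.ones(self.n_participants, bool) if participant_mask is None else np.asarray(participant_mask)
        sm = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeMatrix(
            self.dosages[np.ix_(pm, sm)],
            [p for p, keep in zip(self.participant_ids, pm) if keep],
            self.snps.loc[sm].reset_index(drop=True),
        )

    def subset_snp_ids(self, snp_ids) -> "GenotypeMatrix":
        wanted = set(snp_ids)
        mask = self.snps["id"].isin(wanted).to_numpy()
        return self.subset(snp_mask=mask)


@dataclass
class LipidomeMatrix:
    """Participants x lipid-species concentration matrix.

    ``concentrations`` is a DataFrame indexed by participant id with one
    column per lipid species; ``classes`` maps each species to a lipid class
    (sphingolipid, glycerophospholipid, glycerolipid, sterol, or other).
    """

    concentrations: pd.DataFrame
    classes: pd.Series = field(default=None)

    def __post_init__(self):
        if self.concentrations.columns.duplicated().any():
            raise ConfigurationError("duplicate lipid names")
        if not np.isfinite(self.concentrations.to_numpy(float)).all():
            raise ConfigurationError("lipid concentrations must be finite")
        if self.classes is None:
            self.classes = pd.Series("other", index=self.concentrations.columns)
        self.classes = self.classes.reindex(self.concentrations.columns)

    @property
    def participant_ids(self) -> list:
        return self.concentrations.index.tolist()

    @property
    def lipid_names(self) -> list:
        return self.concentrations.columns.tolist()

    @property
    def n_participants(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_lipids(self) -> int:
        return self.concentrations.shape[1]
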
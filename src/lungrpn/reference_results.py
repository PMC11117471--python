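"""Published LUNA16 detection indicator rows used as consistency fixtures.

Each row records (accuracy, precision, sensitivity, specificity, f1) as
printed, to 4 decimal places, for a backbone / anchor-clustering / setting
combination of a published nodule-detection system.  The rows serve one
purpose here: verifying that the F1 column is the harmonic mean of the
precision and sensitivity columns (to within the +-0.0001 rounding of the
printed inputs).  They are fixtures, not outputs of this package.

One row — MobileNet with k-means anchors at K=5 — is internally inconsistent
in the original source (printed F1 0.9218 vs 0.9169 recomputed from its own
precision/sensitivity); it is flagged ``consistent=False`` and is expected to
fail the check.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceRow", "REFERENCE_ROWS", "WORKED_EXAMPLE_KEYS"]


@dataclass(frozen=True)
class ReferenceRow:
    table: str  # which published table the row comes from
    setting: str  # K = cluster count, or attention variant
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    consistent: bool = True  # False: known printing inconsistency in the source


REFERENCE_ROWS: dict[tuple[str, str, str], ReferenceRow] = {}


def _add(table, backbone, clustering, setting, acc, p, r, spec, f1, consistent=True):
    REFERENCE_ROWS[(backbone, clustering, setting)] = ReferenceRow(
        table, setting, acc, p, r, spec, f1, consistent
    )


# ResNet-50 backbone, k-means anchors, by cluster count K
_add("T1", "resnet", "kmeans", "K3", 0.9287, 0.9146, 0.9414, 0.9167, 0.9278)
_add("T1", "resnet", "kmeans", "K5", 0.9389, 0.9265, 0.9498, 0.9286, 0.9380)
_add("T1", "resnet", "kmeans", "K7", 0.9430, 0.9342, 0.9498, 0.9365, 0.9419)
_add("T1", "resnet", "kmeans", "K9", 0.9409, 0.9339, 0.9456, 0.9365, 0.9397)
# ResNet-50 backbone, fuzzy c-means anchors
_add("T2", "resnet", "fcm", "K3", 0.9348, 0.9259, 0.9414, 0.9286, 0.9336)
_add("T2", "resnet", "fcm", "K5", 0.9491, 0.9421, 0.9540, 0.9444, 0.9480)
_add("T2", "resnet", "fcm", "K7", 0.9450, 0.9380, 0.9498, 0.9405, 0.9439)
_add("T2", "resnet", "fcm", "K9", 0.9389, 0.9336, 0.9414, 0.9365, 0.9375)
# DenseNet-121 backbone, k-means anchors
_add("T3", "densenet", "kmeans", "K3", 0.9145, 0.8988, 0.9289, 0.9008, 0.9136)
_add("T3", "densenet", "kmeans", "K5", 0.9430, 0.9342, 0.9498, 0.9365, 0.9419)
_add("T3", "densenet", "kmeans", "K7", 0.9369, 0.9298, 0.9414, 0.9325, 0.9356)
_add("T3", "densenet", "kmeans", "K9", 0.9348, 0.9259, 0.9414, 0.9286, 0.9336)
# DenseNet-121 backbone, fuzzy c-means anchors
_add("T4", "densenet", "fcm", "K3", 0.9287, 0.9180, 0.9372, 0.9206, 0.9275)
_add("T4", "densenet", "fcm", "K5", 0.9491, 0.9385, 0.9582, 0.9405, 0.9482)
_add("T4", "densenet", "fcm", "K7", 0.9409, 0.9339, 0.9456, 0.9365, 0.9397)
_add("T4", "densenet", "fcm", "K9", 0.9328, 0.9256, 0.9372, 0.9286, 0.9314)
# MobileNet V2 backbone, k-means anchors (K5 row: known printing inconsistency)
_add("T5", "mobilenet", "kmeans", "K3", 0.9104, 0.8980, 0.9205, 0.9008, 0.9091)
_add("T5", "mobilenet", "kmeans", "K5", 0.9226, 0.9069, 0.9272, 0.9087, 0.9218, False)
_add("T5", "mobilenet", "kmeans", "K7", 0.9226, 0.9136, 0.9289, 0.9167, 0.9212)
_add("T5", "mobilenet", "kmeans", "K9", 0.9206, 0.9098, 0.9289, 0.9127, 0.9193)
# MobileNet V2 backbone, fuzzy c-means anchors
_add("T6", "mobilenet", "fcm", "K3", 0.9435, 0.9020, 0.9247, 0.9524, 0.9132)
_add("T6", "mobilenet", "fcm", "K5", 0.9300, 0.8582, 0.9372, 0.9266, 0.8960)
_add("T6", "mobilenet", "fcm", "K7", 0.9300, 0.8610, 0.9331, 0.9286, 0.8956)
_add("T6", "mobilenet", "fcm", "K9", 0.9246, 0.8533, 0.9247, 0.9246, 0.8876)
# MixNet backbone, k-means anchors
_add("T7", "mixnet", "kmeans", "K3", 0.9206, 0.9132, 0.9247, 0.9167, 0.9189)
_add("T7", "mixnet", "kmeans", "K5", 0.9369, 0.9298, 0.9414, 0.9325, 0.9356)
_add("T7", "mixnet", "kmeans", "K7", 0.9348, 0.9295, 0.9372, 0.9325, 0.9333)
_add("T7", "mixnet", "kmeans", "K9", 0.9308, 0.9218, 0.9372, 0.9246, 0.9295)
# MixNet backbone, fuzzy c-means anchors
_add("T8", "mixnet", "fcm", "K3", 0.9246, 0.8479, 0.9331, 0.9206, 0.8884)
_add("T8", "mixnet", "fcm", "K5", 0.9381, 0.8726, 0.9456, 0.9345, 0.9076)
_add("T8", "mixnet", "fcm", "K7", 0.9367, 0.8721, 0.9414, 0.9345, 0.9054)
_add("T8", "mixnet", "fcm", "K9", 0.9314, 0.8615, 0.9372, 0.9286, 0.8978)
# ResNet + FCM (K=5) with attention variants
_add("T9", "resnet", "attention", "none", 0.9491, 0.9421, 0.9540, 0.9444, 0.9480)
_add("T9", "resnet", "attention", "senet", 0.9511, 0.9461, 0.9540, 0.9484, 0.9500)
_add("T9", "resnet", "attention", "ca1", 0.9532, 0.9463, 0.9582, 0.9484, 0.9522)
_add("T9", "resnet", "attention", "ca2", 0.9470, 0.9419, 0.9498, 0.9444, 0.9458)
# DenseNet + FCM (K=5) with attention variants
_add("T10", "densenet", "attention", "none", 0.9491, 0.9385, 0.9582, 0.9405, 0.9482)
_add("T10", "densenet", "attention", "senet", 0.9409, 0.9268, 0.9540, 0.9286, 0.9402)
_add("T10", "densenet", "attention", "ca1", 0.9532, 0.9426, 0.9623, 0.9444, 0.9524)
_add("T10", "densenet", "attention", "ca2", 0.9450, 0.9344, 0.9540, 0.9365, 0.9441)

# The five worked-example rows used by the acceptance checks.
WORKED_EXAMPLE_KEYS: tuple[tuple[str, str, str], ...] = (
    ("resnet", "kmeans", "K7"),
    ("resnet", "fcm", "K5"),
    ("densenet", "fcm", "K5"),
    ("mixnet", "fcm", "K5"),
    ("resnet", "attention", "ca1"),
)
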
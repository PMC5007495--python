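"""Core domain types shared by every pipeline stage."""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class RhDLabel(Enum):
    """The four RhD expression phenotypes, from high to absent expression."""

    D_POS = "D+"
    WEAK_D = "weak D"
    DEL = "DEL"
    D_NEG = "D-"

    @classmethod
    def from_string(cls, s: str) -> "RhDLabel":
        for member in cls:
            if s in (member.name, member.value):
                return member
        raise ValueError(f"unknown RhD label: {s!r}")


class AntibodyChannel(Enum):
    """Fluorescent antibody used to label the D antigen."""

    H41 = "H41"
    BRAD3 = "BRAD3"
    BIRMA_D6 = "BIRMA-D6"

    @classmethod
    def from_string(cls, s: str) -> "AntibodyChannel":
        for member in cls:
            if s in (member.name, member.value):
                return member
        raise ValueError(f"unknown antibody channel: {s!r}")


class Modality(Enum):
    BRIGHT_FIELD = "bright_field"
    FLUORESCENCE = "fluorescence"


@dataclass
class Frame:
    """A single 2-D camera frame in units of camera counts."""

    pixels: np.ndarray
    modality: Modality
    pixel_pitch_um: float = 0.16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"frame must be 2-D, got shape {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ImageStack:
    """One acquisition of a field of view: bright-field frames followed by
    fluorescence frames, in order."""

    frames: np.ndarray  # (n_frames, H, W)
    n_bright_field: int
    pixel_pitch_um: float = 0.16

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("stack must be a (n_frames, H, W) array")
        if not 0 <= self.n_bright_field <= self.frames.shape[0]:
            raise ValueError("n_bright_field out of range")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_fluorescence(self) -> int:
        return self.n_frames - self.n_bright_field

    def bright_field(self, index: int = 0) -> Frame:
        if not 0 <= index < self.n_bright_field:
            raise IndexError(f"bright-field frame {index} out of range")
        return Frame(self.frames[index], Modality.BRIGHT_FIELD, self.pixel_pitch_um)

    def fluorescence(self, index: int = 0) -> Frame:
        if not 0 <= index < self.n_fluorescence:
            raise IndexError(f"fluorescence frame {index} out of range")
        return Frame(
            self.frames[self.n_bright_field + index],
            Modality.FLUORESCENCE,
            self.pixel_pitch_um,
        )
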
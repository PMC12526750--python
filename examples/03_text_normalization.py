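"""Clean noisy ecological text and map vernacular names to Latin binomials.

Field notes and atlas snippets carry repeated punctuation, stray symbols and
colloquial species names.  The cleaner applies an ordered rule list (strip
control characters and emoji, collapse repeats, normalize whitespace); entity
normalization then scans the cleaned text with case-insensitive longest-match
lookup in a synonym dictionary.
"""

from ecotree import SynonymDictionary, clean_text, normalize_entities

raw = "The seven-spot lady beetle!!!   was seen eating APHIDS near the wheat.."
print("raw:    ", raw)
print("cleaned:", clean_text(raw))

dictionary = SynonymDictionary({
    "seven-spot lady beetle": "Coccinella septempunctata",
    "lady beetle": "Coccinellidae",
    "aphids": "Aphidoidea",
    "green peach aphid": "Myzus persicae",
})
cleaned, entities = normalize_entities(raw, dictionary)
print("entities:", sorted(entities))

# The longer alias wins where aliases nest ("seven-spot lady beetle" vs
# "lady beetle"), so the mention resolves to the species, not the family.
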
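remote	SAME_CHUNK
in the past	SAME_CHUNK
in the last	SAME_CHUNK
previous	SAME_CHUNK
former	ONE_AFTER
prior	ONE_AFTER
recovered	ONE_AFTER
distant	ONE_AFTER
past	TWO_BEFORE_TWO_AFTER
until	ALL_BEFORE
inactive	ALL_BEFORE
none since	ALL_BEFORE
discontinued	ONE_AFTER_ELSE_ALL_BEFORE
quit	ONE_AFTER_ELSE_ALL_BEFORE
ago	ONE_AFTER_ELSE_ALL_BEFORE
stopped	ONE_AFTER_ELSE_ALL_BEFORE
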
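speaker,text
PWD,"No, they were pretty good."
CS,Were they [VblAck]?
PWD,Yeah they- you- you could pet them and they wouldn't yelp.
CS,Oh yeah they're horrors aren't they when they yelp [ActListen].
PWD,"No, god that's right, it drives you k- crazy."
CS,It's always the little ones isn't it that do that?
PWD,Yes.
CS,The big ones don't seem to bark a lot [Expand].
PWD,No they don't bark so much.
CS,No [VblAck].
PWD,"No, I- I found that out."
CS,I've got- I've got a labrador at home [SelfDisc].
PWD,Oh yes.
CS,And she doesn't bark.
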
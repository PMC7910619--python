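item,node_id,u1,u2
item_0,21,1,-0.5
item_1,18,0.5,0.5
item_2,2,-1,0
item_3,20,1,-1
item_4,5,-0.5,-1
item_5,0,-1,-1
item_6,16,0.5,-0.5
item_7,22,1,0
item_8,4,-1,1
item_9,8,-0.5,0.5
item_10,10,0,-1
item_11,13,0,0.5
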
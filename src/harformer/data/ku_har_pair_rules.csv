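first,second
Stand,Talk-stand
Stand,Pick
Stand,Jump
Stand,Walk
Stand,Walk-backward
Stand,Walk-circle
Stand,Run
Stand,Stair-up
Stand,Stair-down
Stand,Table-tennis
Sit,Talk-sit
Talk-sit,Sit
Lay,Sit-up
Sit-up,Lay
Talk-stand,Stand
Talk-stand,Pick
Talk-stand,Jump
Talk-stand,Walk
Talk-stand,Walk-backward
Talk-stand,Walk-circle
Talk-stand,Run
Talk-stand,Stair-up
Talk-stand,Stair-down
Talk-stand,Table-tennis
Pick,Stand
Pick,Talk-stand
Pick,Jump
Pick,Walk
Pick,Walk-backward
Pick,Walk-circle
Pick,Run
Pick,Stair-up
Pick,Stair-down
Pick,Table-tennis
Jump,Stand
Jump,Talk-stand
Jump,Pick
Jump,Walk
Jump,Walk-backward
Jump,Walk-circle
Jump,Run
Jump,Stair-up
Jump,Stair-down
Jump,Table-tennis
Walk,Stand
Walk,Talk-stand
Walk,Pick
Walk,Jump
Walk,Walk-circle
Walk,Run
Walk,Stair-up
Walk,Stair-down
Walk,Table-tennis
Walk-backward,Stand
Walk-backward,Talk-stand
Walk-backward,Pick
Walk-backward,Jump
Walk-backward,Table-tennis
Walk-circle,Stand
Walk-circle,Talk-stand
Walk-circle,Pick
Walk-circle,Jump
Walk-circle,Walk
Walk-circle,Run
Walk-circle,Stair-up
Walk-circle,Stair-down
Walk-circle,Table-tennis
Run,Stand
Run,Talk-stand
Run,Pick
Run,Jump
Run,Walk
Run,Walk-circle
Run,Stair-up
Run,Stair-down
Run,Table-tennis
Stair-up,Stand
Stair-up,Talk-stand
Stair-up,Pick
Stair-up,Jump
Stair-up,Walk
Stair-up,Walk-circle
Stair-up,Run
Stair-up,Stair-down
Stair-down,Stand
Stair-down,Talk-stand
Stair-down,Pick
Stair-down,Jump
Stair-down,Walk
Stair-down,Walk-circle
Stair-down,Run
Stair-down,Stair-up
Table-tennis,Stand
Table-tennis,Talk-stand
Table-tennis,Pick
Table-tennis,Jump
Table-tennis,Walk
Table-tennis,Walk-backward
Table-tennis,Walk-circle
Table-tennis,Run
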